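"""Metabolite annotation: accurate-mass (MS1) matching and MS/MS evidence.

MS1 annotation matches an observed m/z against every (compound, adduct) pair
of a compound database within a ppm tolerance (default +/-2 ppm, the usual
FTICR database-search window).  MS/MS annotation checks neutral losses and
diagnostic fragments against class-specific fragmentation rules at ppb-level
tolerance; the classic examples are the trimethylamine (C3H9N) and
phosphocholine (C5H14NO4P) losses of PC/SM/LPC lipids, and the adenine-loss
fragment of ATP.  ``consolidate`` combines both evidence levels and flags
annotations that remain ambiguous.

All rule and database masses are recomputed from molecular formulas at load
time; no m/z value is hard-coded.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .chem import (
    ADDUCTS,
    Formula,
    FormulaError,
    MassError,
    ion_mz,
    mass_error,
    neutral_loss,
    parse_formula,
)

__all__ = [
    "COMPOUND_CLASSES",
    "CompoundRecord",
    "FragmentationRule",
    "AnnotationResult",
    "MsmsMatch",
    "DatabaseError",
    "load_compound_db",
    "load_fragmentation_rules",
    "annotate_ms1",
    "annotate_msms",
    "consolidate",
    "annotation_table",
]

#: Controlled vocabulary of compound classes.
COMPOUND_CLASSES = frozenset(
    {"PC", "LPC", "SM", "PA", "PS", "TG", "GPC", "nucleotide", "other"}
)

_MODES = ("positive", "negative")


class DatabaseError(ValueError):
    """Raised for malformed compound databases or rule tables."""


@dataclass(frozen=True)
class CompoundRecord:
    """One candidate metabolite: formula, class and allowed adducts per mode."""

    compound_id: str
    name: str
    formula: Formula
    compound_class: str
    adducts: dict[str, tuple[str, ...]] = field(compare=False)
    #: MALDI matrix / calibrant-only ion: real peak, but never reported as a
    #: tissue metabolite (excluded from differential analysis downstream).
    is_matrix: bool = False

    def __post_init__(self) -> None:
        if self.compound_class not in COMPOUND_CLASSES:
            raise DatabaseError(
                f"{self.compound_id}: class {self.compound_class!r} not in "
                f"controlled vocabulary"
            )
        if not any(self.adducts.get(m) for m in _MODES):
            raise DatabaseError(f"{self.compound_id}: no allowed adducts")

    def ion_mzs(self, mode: str) -> list[tuple[str, float]]:
        """(adduct name, theoretical m/z) for every allowed adduct in mode."""
        return [
            (a, ion_mz(self.formula, ADDUCTS[a]))
            for a in self.adducts.get(mode, ())
        ]


def _parse_adduct_field(raw: str, mode: str) -> tuple[str, ...]:
    if raw.strip() in ("", "-"):
        return ()
    names = tuple(s.strip() for s in raw.split(";") if s.strip())
    for n in names:
        if n not in ADDUCTS:
            raise DatabaseError(f"unknown adduct {n!r}")
        sign = 1 if mode == "positive" else -1
        if ADDUCTS[n].charge * sign <= 0:
            raise DatabaseError(f"adduct {n!r} has wrong polarity for {mode}")
    return names


def load_compound_db(path: str | Path | None = None) -> list[CompoundRecord]:
    """Load a compound database from TSV.

    Expected header: ``id  name  formula  class  adducts_pos  adducts_neg``
    with adducts ';'-separated ('-' for none).  ``path=None`` loads the
    packaged database of species named in the study (nucleotides, inositol
    phosphates, PC/LPC/SM/PA/PS/TG lipids, carnitines, matrix peaks).
    Duplicate ids and malformed rows raise :class:`DatabaseError` with the
    offending line number.
    """
    if path is None:
        text = resources.files("msimet.data").joinpath("compounds.tsv").read_text()
    else:
        text = Path(path).read_text()
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    required = {"id", "name", "formula", "class", "adducts_pos", "adducts_neg"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise DatabaseError(
            f"compound DB header must contain {sorted(required)}"
        )
    records: list[CompoundRecord] = []
    seen: set[str] = set()
    for lineno, row in enumerate(reader, start=2):
        try:
            cid = row["id"].strip()
            if not cid:
                raise DatabaseError("empty id")
            if cid in seen:
                raise DatabaseError(f"duplicate id {cid!r}")
            seen.add(cid)
            records.append(
                CompoundRecord(
                    compound_id=cid,
                    name=row["name"].strip(),
                    formula=parse_formula(row["formula"]),
                    compound_class=row["class"].strip(),
                    adducts={
                        "positive": _parse_adduct_field(row["adducts_pos"], "positive"),
                        "negative": _parse_adduct_field(row["adducts_neg"], "negative"),
                    },
                    is_matrix=bool(int(row.get("is_matrix") or 0)),
                )
            )
        except (FormulaError, DatabaseError, KeyError, AttributeError) as exc:
            raise DatabaseError(f"line {lineno}: {exc}") from exc
    return records


@dataclass(frozen=True)
class FragmentationRule:
    """A neutral-loss or diagnostic-fragment rule supporting compound classes.

    ``kind`` is either ``neutral_loss`` (the rule mass is the monoisotopic
    mass of the lost neutral) or ``fragment`` (the rule mass is the ion m/z
    of ``formula`` with ``adduct``).  Masses are always recomputed from the
    formula, never stored.
    """

    rule_id: str
    kind: str
    formula: Formula
    adduct: str | None
    tolerance_ppb: float
    classes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("neutral_loss", "fragment"):
            raise DatabaseError(f"{self.rule_id}: unknown rule kind {self.kind!r}")
        if self.tolerance_ppb <= 0:
            raise DatabaseError(f"{self.rule_id}: tolerance must be > 0")
        if self.kind == "fragment" and self.adduct not in ADDUCTS:
            raise DatabaseError(f"{self.rule_id}: fragment rule needs an adduct")

    @property
    def target_mass(self) -> float:
        """Loss mass (Da) for neutral-loss rules, ion m/z for fragment rules."""
        from .chem import monoisotopic_mass

        if self.kind == "neutral_loss":
            return monoisotopic_mass(self.formula)
        return ion_mz(self.formula, ADDUCTS[self.adduct])


def load_fragmentation_rules(
    path: str | Path | None = None,
) -> list[FragmentationRule]:
    """Load fragmentation rules from TSV (packaged defaults when ``path`` is
    None): trimethylamine and phosphocholine losses for choline lipids, and
    the adenine-loss diagnostic fragment for adenosine nucleotides."""
    if path is None:
        text = (
            resources.files("msimet.data")
            .joinpath("fragmentation_rules.tsv")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    rules = []
    for lineno, row in enumerate(reader, start=2):
        try:
            rules.append(
                FragmentationRule(
                    rule_id=row["rule_id"].strip(),
                    kind=row["kind"].strip(),
                    formula=parse_formula(row["formula"]),
                    adduct=None if row["adduct"].strip() in ("", "-") else row["adduct"].strip(),
                    tolerance_ppb=float(row["tolerance_ppb"]),
                    classes=frozenset(
                        s.strip() for s in row["classes"].split(";") if s.strip()
                    ),
                    description=row.get("description", "").strip(),
                )
            )
        except (FormulaError, DatabaseError, KeyError, ValueError) as exc:
            raise DatabaseError(f"line {lineno}: {exc}") from exc
    return rules


@dataclass(frozen=True)
class AnnotationResult:
    """A single (compound, adduct) assignment for an observed m/z."""

    observed_mz: float
    compound_id: str
    name: str
    compound_class: str
    adduct: str
    theoretical_mz: float
    error_ppm: float
    evidence: str = "MS1"  # "MS1" or "MS2"
    n_competitors: int = 0
    ambiguous: bool = False
    is_matrix: bool = False


def annotate_ms1(
    observed_mz: float,
    mode: str,
    db: Sequence[CompoundRecord],
    tolerance_ppm: float = 2.0,
) -> list[AnnotationResult]:
    """All (compound, adduct) candidates within ``tolerance_ppm`` of an
    observed m/z, sorted by |error| ascending, ties broken by compound id.

    An empty list is a valid no-match result.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be > 0")
    if not db:
        raise ValueError("compound database is empty")
    hits: list[AnnotationResult] = []
    for rec in db:
        for adduct_name, theo in rec.ion_mzs(mode):
            err = mass_error(observed_mz, theo)
            if abs(err.ppm) <= tolerance_ppm:
                hits.append(
                    AnnotationResult(
                        observed_mz=observed_mz,
                        compound_id=rec.compound_id,
                        name=rec.name,
                        compound_class=rec.compound_class,
                        adduct=adduct_name,
                        theoretical_mz=theo,
                        error_ppm=err.ppm,
                        is_matrix=rec.is_matrix,
                    )
                )
    hits.sort(key=lambda h: (abs(h.error_ppm), h.compound_id))
    n = len(hits) - 1
    return [replace(h, n_competitors=n) for h in hits]


@dataclass(frozen=True)
class MsmsMatch:
    """A fragmentation rule matched in an MS/MS spectrum."""

    rule: FragmentationRule
    fragment_mz: float
    observed_value: float  # observed loss mass or fragment m/z
    error: MassError


def annotate_msms(
    precursor_mz: float,
    fragment_mzs: Iterable[float],
    mode: str,
    rules: Sequence[FragmentationRule] | None = None,
    tolerance_ppb: float | None = None,
) -> list[MsmsMatch]:
    """Match MS/MS fragments of a singly charged precursor against rules.

    A neutral-loss rule matches a fragment when the observed loss
    (precursor - fragment) is within tolerance of the rule's loss mass; a
    diagnostic-fragment rule matches when a fragment m/z is within tolerance
    of the rule's ion m/z.  ``tolerance_ppb`` overrides the per-rule default
    (500 ppb) when given.  An empty fragment list yields no matches.
    """
    if rules is None:
        rules = load_fragmentation_rules()
    sign = 1 if mode == "positive" else -1
    matches: list[MsmsMatch] = []
    for frag in fragment_mzs:
        for rule in rules:
            tol = tolerance_ppb if tolerance_ppb is not None else rule.tolerance_ppb
            if rule.kind == "neutral_loss":
                if not (0 < frag < precursor_mz):
                    continue
                observed = neutral_loss(precursor_mz, frag)
            else:
                if rule.adduct is not None and ADDUCTS[rule.adduct].charge * sign <= 0:
                    continue
                observed = frag
            err = mass_error(observed, rule.target_mass)
            if abs(err.ppb) <= tol:
                matches.append(
                    MsmsMatch(
                        rule=rule,
                        fragment_mz=frag,
                        observed_value=observed,
                        error=err,
                    )
                )
    return matches


def consolidate(
    ms1: Sequence[AnnotationResult],
    msms: Sequence[MsmsMatch] = (),
) -> AnnotationResult:
    """Combine MS1 candidates with MS/MS evidence into a final annotation.

    * one MS1 candidate, no MS/MS -> MS1-only result;
    * one candidate supported by >=1 rule of its class -> MS2-confirmed;
    * several candidates but the matched rules' supported classes single out
      exactly one -> that candidate, MS2-confirmed;
    * otherwise -> best candidate flagged ambiguous, competitors retained in
      ``n_competitors`` (mirrors keeping only unambiguous identifications).
    """
    if not ms1:
        raise ValueError("consolidate requires a non-empty MS1 candidate list")
    rule_classes: set[str] = set()
    for m in msms:
        rule_classes |= m.rule.classes
    supported = [h for h in ms1 if h.compound_class in rule_classes]
    if len(ms1) == 1:
        best = ms1[0]
        confirmed = bool(supported)
    elif len(supported) == 1:
        best = supported[0]
        confirmed = True
    else:
        # no discriminating MS/MS evidence: keep the best-|error| candidate
        # but flag the annotation as ambiguous; the competitor count covers
        # every candidate sharing the call
        best = ms1[0]
        return replace(best, ambiguous=True, n_competitors=len(ms1))
    return replace(
        best,
        evidence="MS2" if confirmed else "MS1",
        n_competitors=len(ms1) - 1,
        ambiguous=False,
    )


def annotation_table(results: Iterable[AnnotationResult]):
    """Annotation report as a DataFrame (one row per result), ready for CSV."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "observed_mz": r.observed_mz,
                "compound_id": r.compound_id,
                "name": r.name,
                "class": r.compound_class,
                "adduct": r.adduct,
                "theoretical_mz": r.theoretical_mz,
                "error_ppm": r.error_ppm,
                "evidence": r.evidence,
                "n_competitors": r.n_competitors,
                "ambiguous": r.ambiguous,
                "is_matrix": r.is_matrix,
            }
            for r in results
        ]
    )
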