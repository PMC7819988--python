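"""Spectrum preprocessing: recalibration, TIC normalization, peak binning.

The preprocessing chain mirrors standard FTICR imaging practice:

1. **Recalibration** against a list of known calibrant ions (matrix peaks,
   carnitines, nucleotides, abundant lipids).  Single-point calibration
   applies one multiplicative correction that zeroes the error of the
   matched calibrant; the linear model fits a ppm drift vs m/z by least
   squares.  Calibrant theoretical m/z are recomputed from formulas at load
   time and checked against any stored value.
2. **TIC normalization**: every pixel's spectrum is scaled so its total ion
   current equals a common target (the dataset mean TIC by default),
   removing pixel-to-pixel acquisition variation while preserving relative
   intensities within the pixel.
3. **Binning** of peaks across all pixels and samples into features at
   +/-1 ppm: a greedy sorted walk grows a window while each peak stays
   within tolerance of the running intensity-weighted consensus m/z; a
   final full-member check splits any cluster whose extremes drifted out,
   and a prevalence filter drops features seen in too few pixels.

The result is a :class:`FeatureMatrix`: features x samples, each cell the
mean intensity over the sample's pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import ADDUCTS, Formula, ion_mz, parse_formula
from .dataset import MSIDataset, Sample

__all__ = [
    "Calibrant",
    "load_calibrants",
    "RecalibrationResult",
    "recalibrate",
    "recalibrate_dataset",
    "tic_normalize",
    "bin_features",
    "FeatureMatrix",
    "concat_feature_matrices",
    "CalibrationError",
]

logger = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """Raised for invalid calibrant lists or failed recalibration."""


@dataclass(frozen=True)
class Calibrant:
    name: str
    formula: Formula
    adduct: str
    mode: str
    mz: float  # recomputed from formula at load


def load_calibrants(
    path: str | Path | None = None, mode: str | None = None
) -> list[Calibrant]:
    """Load calibrants from TSV (packaged list when ``path`` is None).

    The theoretical m/z is recomputed from the formula and adduct; a stored
    m/z that disagrees by more than 1e-5 Da raises
    :class:`CalibrationError`.
    """
    if path is None:
        text = resources.files("msimet.data").joinpath("calibrants.tsv").read_text()
    else:
        text = Path(path).read_text()
    out = []
    header, *lines = [ln for ln in text.splitlines() if ln.strip()]
    cols = header.split("\t")
    for lineno, line in enumerate(lines, start=2):
        row = dict(zip(cols, line.split("\t")))
        formula = parse_formula(row["formula"])
        theo = ion_mz(formula, ADDUCTS[row["adduct"]])
        stored = row.get("mz", "").strip()
        if stored and abs(float(stored) - theo) > 1e-5:
            raise CalibrationError(
                f"line {lineno}: stored m/z {stored} disagrees with "
                f"recomputed {theo:.6f} for {row['name']}"
            )
        out.append(
            Calibrant(
                name=row["name"],
                formula=formula,
                adduct=row["adduct"],
                mode=row["mode"],
                mz=theo,
            )
        )
    if mode is not None:
        out = [c for c in out if c.mode == mode]
    return out


@dataclass
class RecalibrationResult:
    """Corrected m/z plus the fitted drift model for one spectrum."""

    mz: np.ndarray
    offset_ppm: float | None  # single-point / intercept of the linear model
    slope_ppm_per_da: float = 0.0
    matched: list[str] = field(default_factory=list)
    residual_ppm: dict[str, float] = field(default_factory=dict)
    flagged: bool = False  # True when no calibrant was found


def _match_calibrants(
    mz: np.ndarray,
    intensity: np.ndarray | None,
    calibrants: Sequence[Calibrant],
    search_ppm: float,
) -> list[tuple[Calibrant, float, float]]:
    """Best (calibrant, observed m/z, weight) matches within the window."""
    matches = []
    for cal in calibrants:
        tol = cal.mz * search_ppm * 1e-6
        sel = np.abs(mz - cal.mz) <= tol
        if not np.any(sel):
            continue
        cand = mz[sel]
        w = intensity[sel] if intensity is not None else np.ones(len(cand))
        best = int(np.argmax(w))
        matches.append((cal, float(cand[best]), float(w[best])))
    return matches


def recalibrate(
    mz: np.ndarray,
    intensity: np.ndarray | None,
    calibrants: Sequence[Calibrant],
    model: str = "single-point",
    search_ppm: float = 5.0,
) -> RecalibrationResult:
    """Recalibrate one spectrum against a calibrant list.

    ``single-point`` picks the most intense matched calibrant and applies a
    uniform multiplicative correction zeroing its error; ``linear`` fits
    ppm error vs m/z over >=2 matched calibrants by least squares.  When no
    calibrant is found the spectrum passes through unchanged with
    ``flagged=True``.
    """
    mz = np.asarray(mz, dtype=float)
    matches = _match_calibrants(mz, intensity, calibrants, search_ppm)
    if not matches:
        return RecalibrationResult(mz=mz.copy(), offset_ppm=None, flagged=True)
    if model == "single-point":
        cal, obs, _ = max(matches, key=lambda t: t[2])
        offset = (obs - cal.mz) / cal.mz * 1e6
        corrected = mz / (1.0 + offset * 1e-6)
        slope = 0.0
    elif model == "linear":
        if len(matches) < 2:
            raise CalibrationError("linear recalibration needs >= 2 calibrants")
        xs = np.array([c.mz for c, _, _ in matches])
        errs = np.array([(o - c.mz) / c.mz * 1e6 for c, o, _ in matches])
        slope, offset = np.polyfit(xs, errs, 1)
        corrected = mz / (1.0 + (offset + slope * mz) * 1e-6)
    else:
        raise ValueError(f"unknown recalibration model {model!r}")
    residual = {}
    for cal, _, _ in matches:
        tol = cal.mz * search_ppm * 1e-6
        sel = np.abs(corrected - cal.mz) <= tol
        if np.any(sel):
            best = corrected[sel][int(np.argmin(np.abs(corrected[sel] - cal.mz)))]
            residual[cal.name] = float((best - cal.mz) / cal.mz * 1e6)
    return RecalibrationResult(
        mz=corrected,
        offset_ppm=float(offset),
        slope_ppm_per_da=float(slope),
        matched=[c.name for c, _, _ in matches],
        residual_ppm=residual,
    )


def recalibrate_dataset(
    dataset: MSIDataset,
    calibrants: Sequence[Calibrant] | None = None,
    model: str = "single-point",
    level: str = "sample",
    search_ppm: float = 5.0,
) -> tuple[MSIDataset, pd.DataFrame]:
    """Recalibrate every sample (or every pixel) of a dataset.

    ``level="sample"`` estimates one drift per sample from the median
    calibrant error over all its pixels, the natural granularity when the
    drift is a per-acquisition offset; ``level="pixel"`` applies
    :func:`recalibrate` spectrum by spectrum.  Returns the corrected
    dataset and a per-sample report.
    """
    calibrants = calibrants if calibrants is not None else load_calibrants(
        mode=dataset.mode
    )
    rows = []
    new_samples = []
    for s in dataset:
        if level == "pixel":
            mz_new = s.mz.copy()
            flagged = 0
            offsets = []
            for pix in np.unique(s.pixel_index):
                sel = s.pixel_index == pix
                res = recalibrate(
                    s.mz[sel], s.intensity[sel], calibrants, model, search_ppm
                )
                mz_new[sel] = res.mz
                if res.flagged:
                    flagged += 1
                else:
                    offsets.append(res.offset_ppm)
            offset = float(np.median(offsets)) if offsets else None
            rows.append(
                {
                    "sample": s.sample_id,
                    "offset_ppm": offset,
                    "n_matched_calibrants": len(calibrants),
                    "flagged": flagged > 0 and not offsets,
                }
            )
            new_samples.append(s.with_peaks(mz_new, s.intensity.copy(), s.pixel_index.copy()))
            continue
        # sample level: per-calibrant median error across all pixels
        errors, weights, names = [], [], []
        for cal in calibrants:
            tol = cal.mz * search_ppm * 1e-6
            sel = np.abs(s.mz - cal.mz) <= tol
            if not np.any(sel):
                continue
            errs = (s.mz[sel] - cal.mz) / cal.mz * 1e6
            errors.append(float(np.median(errs)))
            weights.append(float(np.sum(s.intensity[sel])))
            names.append(cal.name)
        if not errors:
            logger.warning("sample %s: no calibrant found; left uncorrected", s.sample_id)
            rows.append(
                {
                    "sample": s.sample_id,
                    "offset_ppm": None,
                    "n_matched_calibrants": 0,
                    "flagged": True,
                }
            )
            new_samples.append(s)
            continue
        if model == "single-point":
            offset = errors[int(np.argmax(weights))]
            mz_new = s.mz / (1.0 + offset * 1e-6)
        elif model == "linear":
            if len(errors) < 2:
                raise CalibrationError(
                    f"sample {s.sample_id}: linear model needs >= 2 calibrants"
                )
            xs = np.array([c.mz for c in calibrants if c.name in names])
            slope, offset = np.polyfit(xs, np.array(errors), 1)
            mz_new = s.mz / (1.0 + (offset + slope * s.mz) * 1e-6)
        else:
            raise ValueError(f"unknown recalibration model {model!r}")
        rows.append(
            {
                "sample": s.sample_id,
                "offset_ppm": float(offset),
                "n_matched_calibrants": len(names),
                "flagged": False,
            }
        )
        new_samples.append(s.with_peaks(mz_new, s.intensity.copy(), s.pixel_index.copy()))
    out = MSIDataset(samples=new_samples, mode=dataset.mode, extra=dict(dataset.extra))
    return out, pd.DataFrame(rows).set_index("sample")


def tic_normalize(dataset: MSIDataset, target: str = "mean") -> MSIDataset:
    """Scale every pixel so its total ion current equals a common target.

    ``target="mean"`` uses the dataset-wide mean TIC (the conventional
    choice); ``target="unit"`` scales every pixel to TIC 1.  Zero-TIC
    pixels are excluded from scaling and logged.  Relative intensities
    within a pixel are preserved exactly.
    """
    if target not in ("mean", "unit"):
        raise ValueError(f"unknown TIC target {target!r}")
    tics = [s.tic() for s in dataset]
    all_tics = np.concatenate(tics) if tics else np.empty(0)
    positive = all_tics[all_tics > 0]
    if target == "mean":
        if len(positive) == 0:
            raise ValueError("dataset has no nonzero-TIC pixel")
        target_tic = float(np.mean(positive))
    else:
        target_tic = 1.0
    new_samples = []
    for s, tic in zip(dataset, tics):
        n_zero = int(np.sum(tic == 0))
        if n_zero:
            logger.warning(
                "sample %s: %d zero-TIC pixels excluded from normalization",
                s.sample_id,
                n_zero,
            )
        scale = np.ones_like(tic)
        nz = tic > 0
        scale[nz] = target_tic / tic[nz]
        new_samples.append(
            s.with_peaks(
                s.mz.copy(), s.intensity * scale[s.pixel_index], s.pixel_index.copy()
            )
        )
    return MSIDataset(samples=new_samples, mode=dataset.mode, extra=dict(dataset.extra))


# ---------------------------------------------------------------------------
# binning


def _split_cluster(
    mz: np.ndarray, w: np.ndarray, tol_ppm: float
) -> list[np.ndarray]:
    """Recursively split a sorted cluster until every member is within
    tolerance of its cluster's intensity-weighted consensus m/z."""
    consensus = float(np.average(mz, weights=w))
    if np.all(np.abs(mz - consensus) <= consensus * tol_ppm * 1e-6):
        return [np.arange(len(mz))]
    if len(mz) == 1:  # pragma: no cover - single peak always within tol
        return [np.arange(1)]
    cut = int(np.argmax(np.diff(mz))) + 1
    left = _split_cluster(mz[:cut], w[:cut], tol_ppm)
    right = _split_cluster(mz[cut:], w[cut:], tol_ppm)
    return left + [idx + cut for idx in right]


def greedy_bin_indices(
    mz_sorted: np.ndarray, w_sorted: np.ndarray, tol_ppm: float
) -> list[np.ndarray]:
    """Cluster an ascending m/z array at +/-``tol_ppm`` of the running
    intensity-weighted consensus; returns index arrays per cluster."""
    clusters: list[np.ndarray] = []
    n = len(mz_sorted)
    start = 0
    wsum = 0.0
    wmz = 0.0
    for i in range(n):
        if i == start:
            wsum = w_sorted[i]
            wmz = w_sorted[i] * mz_sorted[i]
            continue
        consensus = wmz / wsum
        if mz_sorted[i] - consensus <= consensus * tol_ppm * 1e-6:
            wsum += w_sorted[i]
            wmz += w_sorted[i] * mz_sorted[i]
        else:
            clusters.append(np.arange(start, i))
            start = i
            wsum = w_sorted[i]
            wmz = w_sorted[i] * mz_sorted[i]
    if n:
        clusters.append(np.arange(start, n))
    refined: list[np.ndarray] = []
    for cl in clusters:
        for part in _split_cluster(mz_sorted[cl], w_sorted[cl], tol_ppm):
            refined.append(cl[part])
    return refined


@dataclass
class FeatureMatrix:
    """Samples x annotated features of (optionally log) intensities.

    ``intensities``: DataFrame, index = feature id, columns = sample id.
    ``features``: per-feature metadata (consensus m/z, mode, peak counts,
    annotation fields once annotated).  ``samples``: per-sample metadata
    (group, age).
    """

    intensities: pd.DataFrame
    features: pd.DataFrame
    samples: pd.DataFrame
    log: bool = False

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.features.index):
            raise ValueError("feature axes of intensities and features differ")
        if list(self.intensities.columns) != list(self.samples.index):
            raise ValueError("sample axes of intensities and samples differ")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def impute_zeros(self, policy: str = "half-min") -> "FeatureMatrix":
        """Replace zero cells by half the smallest positive intensity in the
        matrix (the standard metabolomics detection floor)."""
        if self.log:
            raise ValueError("impute before log transformation")
        if policy != "half-min":
            raise ValueError(f"unknown imputation policy {policy!r}")
        vals = self.intensities.to_numpy()
        if np.any(vals < 0):
            raise ValueError("negative intensities cannot be imputed")
        pos = vals[vals > 0]
        floor = 0.5 * float(pos.min()) if len(pos) else 0.0
        out = self.intensities.where(self.intensities > 0, floor)
        return FeatureMatrix(
            intensities=out,
            features=self.features.copy(),
            samples=self.samples.copy(),
            log=False,
        )

    def to_dir(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.intensities.to_csv(path / "intensities.csv")
        self.features.to_csv(path / "features.csv")
        self.samples.to_csv(path / "samples.csv")
        (path / "meta.json").write_text(
            pd.Series({"log": self.log}).to_json()
        )
        return path

    @classmethod
    def from_dir(cls, path: str | Path) -> "FeatureMatrix":
        import json

        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        return cls(
            intensities=pd.read_csv(path / "intensities.csv", index_col=0),
            features=pd.read_csv(path / "features.csv", index_col=0),
            samples=pd.read_csv(path / "samples.csv", index_col=0),
            log=bool(meta.get("log", False)),
        )


def bin_features(
    dataset: MSIDataset,
    tolerance_ppm: float = 1.0,
    min_pixel_fraction: float = 0.05,
) -> FeatureMatrix:
    """Bin peaks across all pixels and samples into +/-``tolerance_ppm``
    features and aggregate to a per-sample matrix.

    Every member peak ends within tolerance of its feature's
    intensity-weighted consensus m/z.  Per sample, the feature intensity is
    the mean over the sample's pixels (pixels without the peak contribute
    zero).  Features present in fewer than ``min_pixel_fraction`` of all
    pixels are dropped (sub-ppm jitter tails would otherwise shed one-pixel
    satellite features).  Sample order does not affect the result.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be > 0")
    sample_ids = sorted(dataset.sample_ids)
    sample_pos = {sid: k for k, sid in enumerate(sample_ids)}
    n_pixels = np.array([dataset.sample(sid).n_pixels for sid in sample_ids])
    mz_parts, w_parts, samp_parts = [], [], []
    for s in dataset:
        mz_parts.append(s.mz)
        w_parts.append(s.intensity)
        samp_parts.append(np.full(s.n_peaks, sample_pos[s.sample_id]))
    samples_df = pd.DataFrame(
        {
            "group": [dataset.sample(sid).group for sid in sample_ids],
            "age": [dataset.sample(sid).age for sid in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    prefix = {"positive": "pos", "negative": "neg"}[dataset.mode]
    if not mz_parts or sum(map(len, mz_parts)) == 0:
        empty = pd.DataFrame(index=pd.Index([], name="feature"), columns=sample_ids, dtype=float)
        feats = pd.DataFrame(
            index=pd.Index([], name="feature"),
            columns=["mz", "mode", "n_peaks", "n_samples"],
        )
        return FeatureMatrix(intensities=empty, features=feats, samples=samples_df)
    mz = np.concatenate(mz_parts)
    w = np.concatenate(w_parts)
    samp = np.concatenate(samp_parts)
    order = np.argsort(mz, kind="stable")
    mz, w, samp = mz[order], w[order], samp[order]
    clusters = greedy_bin_indices(mz, w, tolerance_ppm)
    total_px = int(n_pixels.sum())
    rows = []
    mat = []
    for cl in clusters:
        if len(cl) < min_pixel_fraction * total_px:
            continue
        consensus = float(np.average(mz[cl], weights=w[cl]))
        per_sample = np.zeros(len(sample_ids))
        np.add.at(per_sample, samp[cl], w[cl])
        mat.append(per_sample / n_pixels)
        rows.append(
            {
                "mz": consensus,
                "mode": dataset.mode,
                "n_peaks": int(len(cl)),
                "n_samples": int(len(np.unique(samp[cl]))),
            }
        )
    feat_ids = [f"{prefix}_{i:04d}" for i in range(len(rows))]
    features = pd.DataFrame(rows, index=pd.Index(feat_ids, name="feature"))
    intensities = pd.DataFrame(
        np.array(mat) if mat else np.empty((0, len(sample_ids))),
        index=features.index,
        columns=sample_ids,
    )
    return FeatureMatrix(intensities=intensities, features=features, samples=samples_df)


def concat_feature_matrices(matrices: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Stack feature matrices (e.g. positive + negative mode) that share the
    same samples."""
    if not matrices:
        raise ValueError("nothing to concatenate")
    ref = matrices[0].samples
    for fm in matrices[1:]:
        if not fm.samples.index.equals(ref.index):
            raise ValueError("feature matrices have different samples")
        if fm.log != matrices[0].log:
            raise ValueError("cannot mix log and raw matrices")
    return FeatureMatrix(
        intensities=pd.concat([fm.intensities for fm in matrices]),
        features=pd.concat([fm.features for fm in matrices]),
        samples=ref.copy(),
        log=matrices[0].log,
    )
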