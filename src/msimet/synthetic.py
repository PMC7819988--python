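"""Ground-truthed synthetic MSI data emulating the study design.

The generator emulates an imaging-metabolomics case/control study of
dystrophic muscle: nine patient biopsies (children, age ~5.5 +/- 1.9 y) vs
nine adult controls (uniform 28-58 y), measured in positive and negative
MALDI-FTICR modes.  Each pixel of each sample receives one centroided peak
per panel compound at the compound's theoretical adduct m/z perturbed by a
per-sample calibration offset and sub-ppm jitter, with log-normal
intensities:

    log I = base + effect * [patient & differential]
            + age_slope * (age - mean age)
            + sample noise + pixel noise,      I *= pixel TIC scale

The default panel is built from the packaged compound database and plants
27 up- and 7 down-regulated metabolites (21 positive-mode, 13 negative-mode
differential species) among matrix/calibrant peaks and null metabolites,
mirroring the published signature split.  A
:class:`TruthTable<pandas.DataFrame>` records the planted effect of every
panel compound so downstream error rates can be scored exactly.

Randomness is fully reproducible: a single master seed spawns one child
stream per sample (``numpy.random.SeedSequence(seed, spawn_key=(mode_index,
sample_index))``), so regenerating any one sample is stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .annotation import CompoundRecord, load_compound_db
from .chem import ADDUCTS, ion_mz
from .dataset import MSIDataset, Sample

__all__ = [
    "PanelCompound",
    "Cohort",
    "SyntheticConfig",
    "generate_dataset",
    "generate_cohort",
    "default_panels",
    "default_study_config",
    "generate_study",
    "sample_level_sd",
    "DEFAULT_EFFECT",
]

#: Default planted group effect (natural-log units) for differential panel
#: compounds.  e^2.5 ~ 12-fold, consistent with a signature of strongly
#: altered metabolites that cleanly separates the two groups.
DEFAULT_EFFECT = 2.5

# Differential split of the packaged database mirroring the study:
# positive mode, 20 up (choline lipids, TGs) + 1 down (GPC);
# negative mode, 7 up (ADP, PAs, PSs) + 6 down (nucleotides, inositol
# phosphates, PRPP).  Total 27 up / 7 down; 21 positive / 13 negative.
_POS_UP = (
    "lpc_16_0", "lpc_18_0", "lpc_18_1", "lpc_20_4",
    "pc_30_0", "pc_32_0", "pc_34_1", "pc_34_2", "pc_36_2", "pc_36_3",
    "pc_36_4", "pc_38_4", "pc_38_6", "pc_40_6",
    "sm_d34_1", "sm_d36_1", "sm_d38_1", "sm_d42_2",
    "tg_52_2", "tg_54_3",
)
_POS_DOWN = ("gpc",)
_POS_NULL = ("carnitine", "acetylcarnitine", "phosphocholine")
_POS_MATRIX = ("dhb", "dhb_dimer", "dhb_trimer")
_NEG_UP = ("adp", "pa_34_1", "pa_36_2", "pa_38_4", "ps_36_1", "ps_38_4", "ps_40_6")
_NEG_DOWN = ("atp", "a4p", "cmp", "ip4", "ip5", "prpp")
_NEG_NULL = ("pep_409", "pep_524")
_NEG_MATRIX = ("aa_9",)

#: Panel species that are MALDI matrix / background ions rather than tissue
#: metabolites (excluded from differential analysis downstream).
MATRIX_COMPOUNDS = frozenset(_POS_MATRIX + _NEG_MATRIX)


@dataclass(frozen=True)
class PanelCompound:
    """One species planted in every pixel of the synthetic tissue."""

    compound_id: str
    mz: float  # theoretical adduct m/z
    adduct: str
    base_log_intensity: float
    effect: float = 0.0  # log-scale shift in patients; 0 = not differential
    region: Literal["left", "right"] | None = None  # optional spatial mask
    # Multiplier on the per-sample biological noise SD.  Matrix/calibrant
    # ions are not biology: their section-to-section deposition variability
    # is the shared acquisition scale (tic_log_sd), so they get 0 here;
    # with a nonzero value the TIC (matrix-dominated) would carry
    # sample-level noise that normalization re-injects into every analyte.
    sample_noise_scale: float = 1.0


@dataclass(frozen=True)
class Cohort:
    """Sample ids, group labels and ages shared across acquisition modes."""

    sample_ids: tuple[str, ...]
    groups: tuple[str, ...]
    ages: tuple[float, ...]


def generate_cohort(
    seed: int,
    n_per_group: int = 9,
    patient_age_mean: float = 5.5,
    patient_age_sd: float = 1.9,
    control_age_range: tuple[float, float] = (28.0, 58.0),
    balanced_ages: bool = False,
) -> Cohort:
    """Draw the study cohort: controls C1..Cn then patients P1..Pn.

    ``balanced_ages=True`` gives both groups the control age distribution
    (used to measure test power free of the age-group confound the real
    design carries).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(999,)))
    ctrl_ages = rng.uniform(*control_age_range, size=n_per_group)
    if balanced_ages:
        pat_ages = rng.uniform(*control_age_range, size=n_per_group)
    else:
        pat_ages = np.clip(
            rng.normal(patient_age_mean, patient_age_sd, size=n_per_group), 1.5, None
        )
    ids = tuple(f"C{i+1}" for i in range(n_per_group)) + tuple(
        f"P{i+1}" for i in range(n_per_group)
    )
    groups = ("control",) * n_per_group + ("patient",) * n_per_group
    ages = tuple(np.round(np.concatenate([ctrl_ages, pat_ages]), 2).tolist())
    return Cohort(sample_ids=ids, groups=groups, ages=ages)


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic acquisition (one ionization mode).

    Noise defaults: 0.3 ppm m/z jitter (FTICR-grade precision), 0.2
    sample-level and 0.5 pixel-level log-intensity SD, 0.3 log-SD of the
    per-pixel TIC scale, and a ~1 ppm-SD global calibration offset per
    sample.  ``age_slope`` (log-intensity per year, default 0) is a stress
    knob that creates an age-correlated drift confounded with group.
    """

    panel: Sequence[PanelCompound]
    mode: Literal["positive", "negative"] = "positive"
    n_per_group: int = 9
    grid_shape: tuple[int, int] = (40, 40)
    mz_jitter_ppm: float = 0.3
    sample_log_sd: float = 0.2
    pixel_log_sd: float = 0.5
    tic_log_sd: float = 0.3
    calibration_offset_ppm_sd: float = 1.0
    patient_age_mean: float = 5.5
    patient_age_sd: float = 1.9
    control_age_range: tuple[float, float] = (28.0, 58.0)
    age_slope: float = 0.0
    cohort: Cohort | None = None
    seed: int = 0
    mode_index: int = 0  # salts per-sample seeds so modes differ

    def __post_init__(self) -> None:
        for name in ("mz_jitter_ppm", "sample_log_sd", "pixel_log_sd",
                     "tic_log_sd", "calibration_offset_ppm_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.grid_shape) < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        ids = [p.compound_id for p in self.panel]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate compound ids in panel")


def sample_level_sd(config: SyntheticConfig) -> float:
    """Realized SD of a feature's per-sample mean log intensity.

    Sample-level noise plus pixel noise attenuated by averaging over the
    grid; this is the SD against which '2-SD' planted effects are defined.
    """
    n_px = config.grid_shape[0] * config.grid_shape[1]
    return float(np.hypot(config.sample_log_sd, config.pixel_log_sd / np.sqrt(n_px)))


def _truth_table(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for p in config.panel:
        rows.append(
            {
                "compound_id": p.compound_id,
                "mode": config.mode,
                "adduct": p.adduct,
                "mz": p.mz,
                "effect": p.effect,
                "direction": "up" if p.effect > 0 else ("down" if p.effect < 0 else "none"),
                "differential": p.effect != 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("compound_id")


def generate_dataset(config: SyntheticConfig) -> tuple[MSIDataset, pd.DataFrame]:
    """Generate one synthetic MSI dataset plus its ground-truth table.

    Deterministic: the same config (including seed) yields a bit-identical
    dataset.
    """
    cohort = config.cohort or generate_cohort(
        config.seed,
        config.n_per_group,
        config.patient_age_mean,
        config.patient_age_sd,
        config.control_age_range,
    )
    if len(cohort.sample_ids) != 2 * config.n_per_group:
        raise ValueError("cohort size does not match n_per_group")
    nx, ny = config.grid_shape
    n_px = nx * ny
    coords = np.array([(x, y) for x in range(nx) for y in range(ny)])
    panel = list(config.panel)
    theo = np.array([p.mz for p in panel])
    base = np.array([p.base_log_intensity for p in panel])
    eff = np.array([p.effect for p in panel])
    mean_age = float(np.mean(cohort.ages))

    region_mask = np.ones((n_px, len(panel)), dtype=bool)
    for j, p in enumerate(panel):
        if p.region == "left":
            region_mask[:, j] = coords[:, 0] < nx / 2
        elif p.region == "right":
            region_mask[:, j] = coords[:, 0] >= nx / 2

    samples = []
    for i, (sid, group, age) in enumerate(
        zip(cohort.sample_ids, cohort.groups, cohort.ages)
    ):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(config.mode_index, i))
        )
        offset_ppm = rng.normal(0.0, config.calibration_offset_ppm_sd)
        noise_scale = np.array([p.sample_noise_scale for p in panel])
        sample_noise = rng.normal(0.0, config.sample_log_sd, size=len(panel)) * noise_scale
        # age drift is biological, so it scales like the biological sample
        # noise (matrix ions are untouched); a uniform all-species drift
        # would be a sample-level scale that TIC normalization removes
        log_i = (
            base
            + np.where(group == "patient", eff, 0.0)
            + config.age_slope * (age - mean_age) * noise_scale
            + sample_noise
        )
        pixel_noise = rng.normal(0.0, config.pixel_log_sd, size=(n_px, len(panel)))
        jitter = rng.normal(0.0, config.mz_jitter_ppm, size=(n_px, len(panel)))
        tic_scale = np.exp(rng.normal(0.0, config.tic_log_sd, size=n_px))
        mz = theo[None, :] * (1.0 + (offset_ppm + jitter) * 1e-6)
        intensity = np.exp(log_i[None, :] + pixel_noise) * tic_scale[:, None]
        keep = region_mask.ravel()
        pix = np.repeat(np.arange(n_px), len(panel))
        samples.append(
            Sample(
                sample_id=sid,
                group=group,
                age=age,
                shape=(nx, ny),
                coords=coords,
                mz=mz.ravel()[keep],
                intensity=intensity.ravel()[keep],
                pixel_index=pix[keep],
            )
        )
    dataset = MSIDataset(samples=samples, mode=config.mode)
    return dataset, _truth_table(config)


def _panel_from_db(
    db: list[CompoundRecord],
    up: Sequence[str],
    down: Sequence[str],
    null: Sequence[str],
    matrix: Sequence[str],
    mode: str,
    effect: float,
) -> list[PanelCompound]:
    by_id = {r.compound_id: r for r in db}
    panel: list[PanelCompound] = []

    def _add(cid: str, eff: float, base: float, noise_scale: float = 1.0) -> None:
        rec = by_id[cid]
        adduct = rec.adducts[mode][0]
        panel.append(
            PanelCompound(
                compound_id=cid,
                mz=ion_mz(rec.formula, ADDUCTS[adduct]),
                adduct=adduct,
                base_log_intensity=base,
                effect=eff,
                sample_noise_scale=noise_scale,
            )
        )

    # deterministic spread of base intensities across the panel
    for k, cid in enumerate(up):
        _add(cid, effect, 8.5 + 0.15 * (k % 8))
    for k, cid in enumerate(down):
        _add(cid, -effect, 9.0 + 0.15 * (k % 8))
    for k, cid in enumerate(null):
        _add(cid, 0.0, 9.5 + 0.15 * (k % 8))
    # Matrix/calibrant ions dominate the TIC by ~3 orders of magnitude, as
    # in real MALDI spectra; TIC normalization therefore removes per-pixel
    # acquisition scale rather than the biological composition shift.
    for cid in matrix:
        _add(cid, 0.0, 16.0, noise_scale=0.0)
    return panel


def default_panels(
    effect: float = DEFAULT_EFFECT,
    db: list[CompoundRecord] | None = None,
) -> dict[str, list[PanelCompound]]:
    """The study-design panels per mode: 27 up / 7 down differential species
    plus null metabolites and matrix/calibrant peaks, from the packaged DB."""
    db = db if db is not None else load_compound_db()
    return {
        "positive": _panel_from_db(
            db, _POS_UP, _POS_DOWN, _POS_NULL, _POS_MATRIX, "positive", effect
        ),
        "negative": _panel_from_db(
            db, _NEG_UP, _NEG_DOWN, _NEG_NULL, _NEG_MATRIX, "negative", effect
        ),
    }


def default_study_config(
    seed: int = 0,
    effect: float = DEFAULT_EFFECT,
    grid_shape: tuple[int, int] = (40, 40),
    n_per_group: int = 9,
    balanced_ages: bool = False,
    **overrides,
) -> dict[str, SyntheticConfig]:
    """Per-mode configs for the default two-mode study, sharing one cohort."""
    cohort = generate_cohort(seed, n_per_group, balanced_ages=balanced_ages)
    panels = default_panels(effect=effect)
    return {
        mode: SyntheticConfig(
            panel=panels[mode],
            mode=mode,
            n_per_group=n_per_group,
            grid_shape=grid_shape,
            cohort=cohort,
            seed=seed,
            mode_index=idx,
            **overrides,
        )
        for idx, mode in enumerate(("positive", "negative"))
    }


def generate_study(
    seed: int = 0, **kwargs
) -> dict[str, tuple[MSIDataset, pd.DataFrame]]:
    """Generate the full default study: both modes, one shared cohort."""
    configs = default_study_config(seed=seed, **kwargs)
    return {mode: generate_dataset(cfg) for mode, cfg in configs.items()}
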