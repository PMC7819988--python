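"""Scoring pipeline output against synthetic ground truth.

The synthetic generator's truth table makes error rates exactly measurable:
these helpers match binned features back to planted compounds by m/z,
score a differential-analysis table (true/false discoveries, realized
false-discovery proportion, per-feature power, direction agreement), and
run the replicate Monte-Carlos used to validate the statistical pipeline
(power at 2-SD effects, null-calibration under zero effects).

"2-SD effect" means twice the realized per-feature sample-level SD of log
intensity — measured from a zero-effect calibration run through the full
preprocessing chain, because normalization and pixel averaging contribute
noise beyond the generative sample-level SD.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .preprocess import (
    FeatureMatrix,
    bin_features,
    concat_feature_matrices,
    load_calibrants,
    recalibrate_dataset,
    tic_normalize,
)
from .stats import differential_analysis, log_transform
from .synthetic import (
    MATRIX_COMPOUNDS,
    default_panels,
    default_study_config,
    generate_dataset,
)

__all__ = [
    "preprocess_study",
    "match_truth",
    "analyte_features",
    "RunScore",
    "score_run",
    "realized_feature_sd",
    "power_at_2sd",
    "null_calibration",
]


def preprocess_study(
    seed: int,
    effect_scale: float,
    grid_shape: tuple[int, int] = (8, 8),
    balanced_ages: bool = False,
    n_per_group: int = 9,
    **config_overrides,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Generate the two-mode study with all planted effects multiplied by
    ``effect_scale`` (truth effects are defined at scale 1), then
    recalibrate, TIC-normalize, bin and impute.  Returns the raw feature
    matrix and the combined truth table."""
    configs = default_study_config(
        seed=seed,
        effect=1.0,
        grid_shape=grid_shape,
        n_per_group=n_per_group,
        balanced_ages=balanced_ages,
        **config_overrides,
    )
    fms, truths = [], []
    for mode, cfg in configs.items():
        cfg = replace(
            cfg, panel=[replace(p, effect=p.effect * effect_scale) for p in cfg.panel]
        )
        ds, truth = generate_dataset(cfg)
        recal, _ = recalibrate_dataset(ds, load_calibrants(mode=mode))
        fms.append(bin_features(tic_normalize(recal)))
        truths.append(truth)
    return concat_feature_matrices(fms).impute_zeros(), pd.concat(truths)


def match_truth(
    features: pd.DataFrame, truth: pd.DataFrame, tolerance_ppm: float = 2.0
) -> pd.Series:
    """Map each binned feature to the planted compound whose theoretical m/z
    is nearest within ``tolerance_ppm`` (same mode); NaN when none is."""
    out = {}
    for fid, row in features.iterrows():
        cand = truth[truth["mode"] == row["mode"]]
        dev = (cand["mz"] - row["mz"]).abs()
        idx = dev.idxmin()
        out[fid] = idx if dev.loc[idx] <= row["mz"] * tolerance_ppm * 1e-6 else np.nan
    return pd.Series(out, name="true_compound")


def analyte_features(fm: FeatureMatrix, truth: pd.DataFrame) -> FeatureMatrix:
    """Drop features mapping to matrix/background ions, mirroring the
    pipeline's exclusion of non-metabolite peaks from the analysis."""
    mapping = match_truth(fm.features, truth)
    keep = ~mapping.isin(MATRIX_COMPOUNDS)
    return FeatureMatrix(
        intensities=fm.intensities.loc[keep],
        features=fm.features.loc[keep],
        samples=fm.samples,
        log=fm.log,
    )


@dataclass
class RunScore:
    """Confusion summary of one differential run against planted truth."""

    n_true: int  # differential compounds represented among features
    n_significant: int
    true_positives: int
    false_positives: int
    n_up: int  # significant & direction up
    n_down: int
    direction_correct: bool  # all true positives have the planted sign

    @property
    def fdp(self) -> float:
        """Realized false-discovery proportion (0 when nothing is called)."""
        return self.false_positives / max(self.n_significant, 1)

    @property
    def power(self) -> float:
        """Fraction of planted differential compounds detected."""
        return self.true_positives / max(self.n_true, 1)


def score_run(
    stats_table: pd.DataFrame, features: pd.DataFrame, truth: pd.DataFrame
) -> RunScore:
    """Score a differential-analysis table (indexed like ``features``)."""
    mapping = match_truth(features, truth)
    res = stats_table.join(features[["mz", "mode"]], rsuffix="_feat")
    res = res.join(mapping)
    res = res.join(truth[["effect", "differential"]], on="true_compound")
    res["differential"] = res["differential"].fillna(False)
    sig = res[res["significant"]]
    tp = sig[sig["differential"]]
    direction_ok = bool(
        ((tp["effect"] > 0) == (tp["direction"] == "up")).all()
    )
    return RunScore(
        n_true=int(res["differential"].sum()),
        n_significant=int(len(sig)),
        true_positives=int(len(tp)),
        false_positives=int(len(sig) - len(tp)),
        n_up=int((sig["direction"] == "up").sum()),
        n_down=int((sig["direction"] == "down").sum()),
        direction_correct=direction_ok,
    )


def realized_feature_sd(
    seed: int,
    grid_shape: tuple[int, int] = (8, 8),
    balanced_ages: bool = True,
    n_calibration: int = 3,
) -> float:
    """Realized within-group SD of log feature intensity under zero effects,
    for the features that carry planted effects.

    Root of the mean pooled within-group variance (unbiased for sigma^2)
    over ``n_calibration`` independent zero-effect runs, restricted to
    features mapping to differential-capable compounds; matrix and
    calibrant features are excluded because their noise model differs."""
    panels = default_panels(effect=1.0)
    diff_compounds = {
        p.compound_id for panel in panels.values() for p in panel if p.effect != 0
    }
    variances = []
    for r in range(n_calibration):
        fm, truth = preprocess_study(seed + r, 0.0, grid_shape, balanced_ages)
        keep = match_truth(fm.features, truth).isin(diff_compounds)
        lg = log_transform(fm)
        groups = lg.samples["group"]
        for g in groups.unique():
            cols = groups.index[groups == g]
            variances.append(lg.intensities.loc[keep, cols].var(axis=1))
    return float(np.sqrt(pd.concat(variances).mean()))


def power_at_2sd(
    seed: int,
    n_replicates: int = 40,
    grid_shape: tuple[int, int] = (8, 8),
    alpha: float = 0.05,
    fdr_method: str = "by",
    n_calibration: int = 3,
) -> float:
    """Monte-Carlo per-feature power of the covariate-adjusted test at
    planted effects of twice the realized feature SD, n = 9 vs 9.

    Age distributions are balanced across groups so the estimate measures
    the test's power rather than the age-group confound of the emulated
    cohort design (controls are adults, patients children).
    """
    effect = 2.0 * realized_feature_sd(seed, grid_shape, n_calibration=n_calibration)
    powers = []
    for r in range(n_replicates):
        fm, truth = preprocess_study(
            seed + 101 + r, effect, grid_shape, balanced_ages=True
        )
        fm = analyte_features(fm, truth)
        res = differential_analysis(
            log_transform(fm), alpha=alpha, fdr_method=fdr_method
        )
        powers.append(score_run(res, fm.features, truth).power)
    return float(np.mean(powers))


def null_calibration(
    seed: int,
    n_replicates: int = 50,
    grid_shape: tuple[int, int] = (6, 6),
    alpha: float = 0.05,
    fdr_method: str = "by",
) -> tuple[np.ndarray, int]:
    """Zero-effect replicates: pooled raw p values (should be uniform) and
    the number of replicates with any BY-significant feature (should be
    rare: the step-up procedure controls FDR at ``alpha`` even under the
    global null)."""
    pvals, reps_with_hits = [], 0
    for r in range(n_replicates):
        fm, truth = preprocess_study(seed + r, 0.0, grid_shape, balanced_ages=False)
        fm = analyte_features(fm, truth)
        res = differential_analysis(
            log_transform(fm), alpha=alpha, fdr_method=fdr_method
        )
        pvals.extend(res["p"].dropna().tolist())
        reps_with_hits += int(res["significant"].sum() > 0)
    return np.asarray(pvals), reps_with_hits
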