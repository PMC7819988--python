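"""End-to-end orchestration: simulate/ingest -> preprocess -> annotate ->
test -> cluster/correlate -> render, with a reproducible run manifest.

A :class:`PipelineConfig` captures every tolerance and option (defaults
follow the study parameters: +/-2 ppm MS1 matching, +/-1 ppm binning,
alpha = 0.05 with Benjamini–Yekutieli correction).  ``run_pipeline`` is a
pure function of (config, seed): identical inputs produce bit-identical
CSV outputs, and the manifest records the resolved config, library
versions, per-stage counts and SHA-256 checksums of every file written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import annotate_ms1, consolidate, load_compound_db
from .dataset import MSIDataset, read_dataset
from .preprocess import (
    FeatureMatrix,
    bin_features,
    concat_feature_matrices,
    load_calibrants,
    recalibrate_dataset,
    tic_normalize,
)
from .stats import differential_analysis, hierarchical_cluster, log_transform, spearman_matrix
from .synthetic import DEFAULT_EFFECT, generate_study

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "PipelineResult",
    "run_pipeline",
    "IonImage",
    "ion_image",
    "render_ion_image",
]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Resolved options of one pipeline run; echoed into the manifest."""

    source: str = "synthetic"  # synthetic | csv | imzml
    dataset_paths: dict = field(default_factory=dict)  # mode -> path
    compound_db: str | None = None  # None = packaged
    calibrants: str | None = None  # None = packaged
    seed: int = 0
    n_per_group: int = 9
    grid_shape: tuple[int, int] = (40, 40)
    effect: float = DEFAULT_EFFECT
    ms1_tolerance_ppm: float = 2.0
    msms_tolerance_ppb: float = 500.0
    binning_ppm: float = 1.0
    recalibration_model: str = "single-point"
    tic_target: str = "mean"
    alpha: float = 0.05
    fdr_method: str = "by"
    linkage: str = "complete"
    n_images: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("ms1_tolerance_ppm", "msms_tolerance_ppb", "binning_ppm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        self.grid_shape = tuple(self.grid_shape)  # type: ignore[assignment]
        if self.source not in ("synthetic", "csv", "imzml"):
            raise ValueError(f"unknown source {self.source!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d


@dataclass
class PipelineResult:
    feature_matrix: FeatureMatrix  # log scale, annotated features
    stats: pd.DataFrame
    correlation: pd.DataFrame | None
    clustering: object | None
    truth: pd.DataFrame | None
    manifest: dict
    outdir: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _validate_inputs(config: PipelineConfig) -> None:
    if config.compound_db is not None and not Path(config.compound_db).exists():
        raise PipelineError("config", f"compound DB not found: {config.compound_db}")
    if config.calibrants is not None and not Path(config.calibrants).exists():
        raise PipelineError("config", f"calibrant list not found: {config.calibrants}")
    if config.source != "synthetic":
        if not config.dataset_paths:
            raise PipelineError("config", "dataset_paths required for non-synthetic source")
        for mode, p in config.dataset_paths.items():
            if not Path(p).exists():
                raise PipelineError("config", f"dataset path for {mode} not found: {p}")


def _annotate_features(
    features: pd.DataFrame, db, tolerance_ppm: float
) -> pd.DataFrame:
    rows = []
    for fid, row in features.iterrows():
        hits = annotate_ms1(row["mz"], row["mode"], db, tolerance_ppm)
        if not hits:
            rows.append(
                {
                    "feature": fid,
                    "compound_id": None,
                    "name": None,
                    "class": None,
                    "adduct": None,
                    "error_ppm": np.nan,
                    "evidence": "none",
                    "n_competitors": 0,
                    "ambiguous": False,
                    "is_matrix": False,
                }
            )
            continue
        final = consolidate(hits)
        rows.append(
            {
                "feature": fid,
                "compound_id": final.compound_id,
                "name": final.name,
                "class": final.compound_class,
                "adduct": final.adduct,
                "error_ppm": final.error_ppm,
                "evidence": final.evidence,
                "n_competitors": final.n_competitors,
                "ambiguous": final.ambiguous,
                "is_matrix": final.is_matrix,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Run every stage and write the results bundle into ``outdir``.

    Outputs: ``feature_matrix/`` (CSV + metadata), ``annotations.csv``,
    ``stats.csv``, ``spearman.csv``, ``linkage.newick``, ``clusters.csv``,
    ``images/*.png``, ``truth.csv`` (synthetic runs) and ``manifest.json``.
    """
    _validate_inputs(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    stage = "input"
    try:
        truth_frames = []
        datasets: dict[str, MSIDataset] = {}
        if config.source == "synthetic":
            study = generate_study(
                seed=config.seed,
                effect=config.effect,
                grid_shape=config.grid_shape,
                n_per_group=config.n_per_group,
            )
            for mode, (ds, truth) in study.items():
                datasets[mode] = ds
                truth_frames.append(truth)
        else:
            for mode, p in config.dataset_paths.items():
                datasets[mode] = read_dataset(p, format=None)
        counts["input"] = {
            m: {"samples": len(d), "pixels": d.total_pixels(), "peaks": d.total_peaks()}
            for m, d in datasets.items()
        }

        stage = "preprocess"
        matrices = []
        normalized: dict[str, MSIDataset] = {}
        for mode, ds in datasets.items():
            cals = load_calibrants(config.calibrants, mode=mode)
            recal, report = recalibrate_dataset(
                ds, cals, model=config.recalibration_model
            )
            norm = tic_normalize(recal, target=config.tic_target)
            normalized[mode] = norm
            fm = bin_features(norm, tolerance_ppm=config.binning_ppm)
            matrices.append(fm)
            counts.setdefault("preprocess", {})[mode] = {
                "features": fm.n_features,
                "median_offset_ppm": float(report["offset_ppm"].median()),
            }
        fm_raw = concat_feature_matrices(matrices).impute_zeros()

        stage = "annotate"
        db = load_compound_db(config.compound_db)
        ann = _annotate_features(fm_raw.features, db, config.ms1_tolerance_ppm)
        fm_raw.features = fm_raw.features.join(ann)
        counts["annotate"] = {
            "features": int(fm_raw.n_features),
            "annotated": int(ann["compound_id"].notna().sum()),
            "ambiguous": int(ann["ambiguous"].sum()),
        }

        stage = "stats"
        # matrix/calibrant ions are instrument background, not tissue
        # metabolites: they are annotated and exported but excluded from the
        # differential analysis (under TIC normalization a global analyte
        # shift would otherwise surface as a spurious matrix "change")
        fm_log = log_transform(fm_raw)
        analyte = fm_log.features.index[~fm_log.features["is_matrix"].fillna(False)]
        analyte_fm = FeatureMatrix(
            intensities=fm_log.intensities.loc[analyte],
            features=fm_log.features.loc[analyte],
            samples=fm_log.samples,
            log=True,
        )
        res = differential_analysis(
            analyte_fm, alpha=config.alpha, fdr_method=config.fdr_method
        )
        stats_table = fm_log.features.loc[analyte].join(res)
        sig = stats_table.index[stats_table["significant"]].tolist()
        counts["stats"] = {
            "features": int(len(stats_table)),
            "matrix_excluded": int(fm_log.n_features - len(analyte)),
            "significant": int(len(sig)),
            "up": int((stats_table["significant"] & (stats_table["direction"] == "up")).sum()),
            "down": int((stats_table["significant"] & (stats_table["direction"] == "down")).sum()),
        }

        stage = "cluster"
        correlation = None
        clustering = None
        if len(sig) >= 2:
            sig_fm = FeatureMatrix(
                intensities=fm_log.intensities.loc[sig],
                features=fm_log.features.loc[sig],
                samples=fm_log.samples,
                log=True,
            )
            correlation = spearman_matrix(sig_fm)
            clustering = hierarchical_cluster(fm_log, features=sig, method=config.linkage)

        stage = "images"
        image_files = []
        img_dir = outdir / "images"
        top = stats_table.loc[sig].sort_values("p_adj").head(config.n_images)
        if len(top):
            img_dir.mkdir(exist_ok=True)
        for fid, row in top.iterrows():
            ds = normalized[row["mode"]]
            for sid in (ds.sample_ids[0], ds.sample_ids[-1]):
                img = ion_image(ds, sid, row["mz"], tolerance_ppm=config.binning_ppm)
                f = img_dir / f"{fid}_{sid}.png"
                render_ion_image(img, f, scale="log")
                image_files.append(f)

        stage = "write"
        fm_log.to_dir(outdir / "feature_matrix")
        ann.to_csv(outdir / "annotations.csv")
        stats_table.to_csv(outdir / "stats.csv")
        if correlation is not None:
            correlation.to_csv(outdir / "spearman.csv")
        if clustering is not None:
            (outdir / "linkage.newick").write_text(clustering.to_newick() + "\n")
            pd.DataFrame(
                {"sample": clustering.sample_ids, "cluster": clustering.labels}
            ).to_csv(outdir / "clusters.csv", index=False)
        truth = pd.concat(truth_frames) if truth_frames else None
        if truth is not None:
            truth.to_csv(outdir / "truth.csv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    files = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "package": {"name": "msimet", "version": __version__},
        "versions": _library_versions(),
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": counts,
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return PipelineResult(
        feature_matrix=fm_log,
        stats=stats_table,
        correlation=correlation,
        clustering=clustering,
        truth=truth,
        manifest=manifest,
        outdir=outdir,
    )


def _library_versions() -> dict:
    import matplotlib
    import scipy
    import sklearn
    import statsmodels

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "scikit-learn": sklearn.__version__,
        "matplotlib": matplotlib.__version__,
    }


# ---------------------------------------------------------------------------
# ion images


@dataclass
class IonImage:
    """Per-pixel intensity map of one m/z window for one sample."""

    sample_id: str
    center_mz: float
    tolerance_ppm: float
    grid: np.ndarray  # (nx, ny), >= 0

    def __post_init__(self) -> None:
        if np.any(self.grid < 0):
            raise ValueError("ion image intensities must be non-negative")


def ion_image(
    dataset: MSIDataset,
    sample_id: str,
    center_mz: float,
    tolerance_ppm: float = 1.0,
) -> IonImage:
    """Summed intensity of peaks within +/-``tolerance_ppm`` of
    ``center_mz``, per pixel; pixels without a matching peak are 0."""
    s = dataset.sample(sample_id)  # KeyError for unknown sample
    tol = center_mz * tolerance_ppm * 1e-6
    sel = np.abs(s.mz - center_mz) <= tol
    flat = np.zeros(s.n_pixels)
    np.add.at(flat, s.pixel_index[sel], s.intensity[sel])
    nx, ny = s.shape
    grid = np.zeros((nx, ny))
    grid[s.coords[:, 0], s.coords[:, 1]] = flat
    return IonImage(
        sample_id=sample_id, center_mz=center_mz, tolerance_ppm=tolerance_ppm, grid=grid
    )


def render_ion_image(
    image: IonImage, path: str | Path, scale: str = "linear", cmap: str = "viridis"
) -> Path:
    """Write an ion image as PNG (linear or log display scale)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    grid = image.grid
    if scale == "log":
        grid = np.log1p(grid)
    elif scale != "linear":
        raise ValueError(f"unknown render scale {scale!r}")
    path = Path(path)
    plt.imsave(path, grid.T, cmap=cmap, origin="lower")
    return path
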