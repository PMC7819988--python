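"""Differential analysis, FDR control, co-expression and clustering.

The group comparison is a per-feature ordinary least-squares fit of
log intensity on a group indicator plus age,

    log I = b0 + b1 * patient + b2 * age + eps,

with the two-sided t test of b1 on n - 3 residual degrees of freedom — the
standard operationalization of "t-test with age as covariate".  Multiple
testing is corrected with the Benjamini–Yekutieli step-up procedure by
default (valid under the arbitrary dependence that correlated metabolites
exhibit; it inflates Benjamini–Hochberg by the harmonic factor
c(m) = sum 1/k), with plain BH selectable.  Co-expression uses Spearman
rank correlation; sample clustering uses agglomerative linkage on Euclidean
distances.

Because every feature shares one design matrix, the OLS fits are solved for
all features at once; the result is identical to fitting each feature with
statsmodels (checked in the test suite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .preprocess import FeatureMatrix

__all__ = [
    "log_transform",
    "differential_test",
    "adjust_benjamini_yekutieli",
    "adjust_pvalues",
    "differential_analysis",
    "spearman_matrix",
    "hierarchical_cluster",
    "ClusteringResult",
]


def log_transform(matrix: FeatureMatrix) -> FeatureMatrix:
    """Natural-log transform every cell; metadata is preserved.

    Cells must be strictly positive (apply the imputation policy first);
    the first offending feature/sample pair is named in the error.
    """
    if matrix.log:
        raise ValueError("matrix is already log-transformed")
    vals = matrix.intensities
    bad = vals <= 0
    if bad.to_numpy().any():
        feat = bad.any(axis=1).idxmax()
        samp = bad.loc[feat].idxmax()
        raise ValueError(
            f"non-positive intensity at feature {feat!r}, sample {samp!r}; "
            "impute zeros before log transformation"
        )
    return FeatureMatrix(
        intensities=np.log(vals),
        features=matrix.features.copy(),
        samples=matrix.samples.copy(),
        log=True,
    )


def differential_test(
    matrix: FeatureMatrix,
    case: str = "patient",
    covariates: tuple[str, ...] = ("age",),
) -> pd.DataFrame:
    """Per-feature OLS group test on a log feature matrix.

    Returns a DataFrame indexed by feature with columns ``estimate`` (the
    case-minus-reference log-intensity difference adjusted for the
    covariates), ``t``, ``p`` and ``df``.  A rank-deficient design (e.g.
    a covariate perfectly collinear with the group indicator) yields
    missing p values with a warning rather than an exception.
    """
    if not matrix.log:
        raise ValueError("differential_test expects a log-transformed matrix")
    groups = matrix.samples["group"]
    levels = sorted(groups.unique())
    if len(levels) != 2 or case not in levels:
        raise ValueError(f"need two groups including {case!r}, got {levels}")
    if min((groups == g).sum() for g in levels) < 2:
        raise ValueError("each group needs at least 2 samples")
    n = matrix.n_samples
    cols = [np.ones(n), (groups == case).to_numpy(float)]
    for cov in covariates:
        vals = matrix.samples[cov].to_numpy(float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"covariate {cov!r} has non-finite values")
        cols.append(vals)
    X = np.column_stack(cols)
    p_params = X.shape[1]
    Y = matrix.intensities.to_numpy().T  # samples x features
    df = n - p_params
    if df < 1:
        raise ValueError("not enough residual degrees of freedom")
    if np.linalg.matrix_rank(X) < p_params:
        warnings.warn("singular design matrix; p values set to missing")
        out = pd.DataFrame(
            {
                "estimate": np.nan,
                "t": np.nan,
                "p": np.nan,
                "df": df,
            },
            index=matrix.features.index,
        )
        return out
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    # exact fits (e.g. a constant feature) leave only rounding error in the
    # residual; treat them as zero-residual rather than dividing noise by
    # noise
    scale = np.maximum(np.mean(Y * Y, axis=0), 1.0)
    exact = rss <= n * 1e-24 * scale
    est = beta[1].copy()
    est[exact & (np.abs(est) <= 1e-9 * np.sqrt(scale))] = 0.0
    s2 = np.where(exact, 0.0, rss / df)
    se = np.sqrt(s2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / np.where(se > 0, se, 1.0), 0.0)
        t = np.where((se == 0) & (est != 0), np.sign(est) * np.inf, t)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return pd.DataFrame(
        {"estimate": est, "t": t, "p": p, "df": df},
        index=matrix.features.index,
    )


def adjust_benjamini_yekutieli(pvalues) -> np.ndarray:
    """Benjamini–Yekutieli step-up adjusted p values (arbitrary dependence).

    adj(i) = min_{j >= i} ( m * c(m) * p_(j) / j ) capped at 1, with
    c(m) = sum_{k=1..m} 1/k.  Missing p values propagate as missing and are
    excluded from m.
    """
    return adjust_pvalues(pvalues, method="by")


def adjust_pvalues(pvalues, method: str = "by") -> np.ndarray:
    """BY (default) or BH adjusted p values; NaNs propagate."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if method not in ("by", "bh"):
        raise ValueError(f"unknown FDR method {method!r}")
    if ok.sum():
        _, adj, _, _ = multipletests(
            p[ok], alpha=0.05, method={"by": "fdr_by", "bh": "fdr_bh"}[method]
        )
        out[ok] = adj
    return out


def differential_analysis(
    matrix: FeatureMatrix,
    case: str = "patient",
    covariates: tuple[str, ...] = ("age",),
    alpha: float = 0.05,
    fdr_method: str = "by",
) -> pd.DataFrame:
    """Group test + FDR adjustment + direction/significance flags.

    One row per feature: estimate, t, p, p_adj, direction (up/down in the
    case group), significant (adjusted p < alpha).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    res = differential_test(matrix, case=case, covariates=covariates)
    res["p_adj"] = adjust_pvalues(res["p"].to_numpy(), method=fdr_method)
    res["direction"] = np.where(res["estimate"] > 0, "up", "down")
    res.loc[res["estimate"] == 0, "direction"] = "none"
    res["significant"] = (res["p_adj"] < alpha).fillna(False)
    res["fdr_method"] = fdr_method
    return res


def spearman_matrix(matrix: FeatureMatrix) -> pd.DataFrame:
    """Pairwise Spearman rho between features (average-rank ties).

    Requires >= 3 samples.  Zero-variance features have undefined rank
    correlation; their rows and columns are missing.
    """
    if matrix.n_samples < 3:
        raise ValueError("Spearman correlation needs >= 3 samples")
    Y = matrix.intensities.to_numpy()  # features x samples
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if matrix.n_features == 1:
            rho = np.ones((1, 1))
        elif matrix.n_features == 2:  # spearmanr returns a scalar here
            r, _ = sps.spearmanr(Y[0], Y[1])
            rho = np.array([[1.0, r], [r, 1.0]])
        else:
            rho, _ = sps.spearmanr(Y, axis=1)
    const = np.std(Y, axis=1) == 0
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    np.fill_diagonal(rho, np.where(const, np.nan, 1.0))
    return pd.DataFrame(rho, index=matrix.features.index, columns=matrix.features.index)


@dataclass
class ClusteringResult:
    """Agglomerative sample clustering: linkage tree plus a k=2 cut."""

    sample_ids: list[str]
    linkage: np.ndarray  # scipy linkage matrix
    labels: np.ndarray  # flat cluster labels at k = 2
    method: str
    metric: str = "euclidean"

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """The linkage tree in Newick, branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float | None) -> str:
            if node.is_leaf():
                label = self.sample_ids[node.id]
                height = 0.0
            else:
                label = f"({walk(node.left, node.dist)},{walk(node.right, node.dist)})"
                height = node.dist
            if parent_height is None:
                return label
            return f"{label}:{max(parent_height - height, 0.0):.6g}"

        return walk(tree, None) + ";"


def hierarchical_cluster(
    matrix: FeatureMatrix,
    features: list[str] | None = None,
    method: str = "complete",
    metric: str = "euclidean",
) -> ClusteringResult:
    """Cluster samples on their feature vectors (Euclidean, complete linkage
    by default; ward/average/single selectable).

    Samples are ordered lexicographically by id before linkage so ties are
    broken deterministically.  ``features`` restricts the profile to a
    subset (typically the significant features).
    """
    if matrix.n_samples < 2:
        raise ValueError("clustering needs at least 2 samples")
    ids = sorted(matrix.samples.index)
    sub = matrix.intensities[ids]
    if features is not None:
        if not len(features):
            raise ValueError("empty feature subset")
        sub = sub.loc[features]
    X = sub.to_numpy().T  # samples x features
    dist = pdist(X, metric=metric)
    Z = hierarchy.linkage(dist, method=method)
    labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    return ClusteringResult(
        sample_ids=ids, linkage=Z, labels=labels, method=method, metric=metric
    )
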