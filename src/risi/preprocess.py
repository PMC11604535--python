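"""Four-step bulk preprocessing applied before program-level inference.

Steps: (1) missing-data policy with regime chosen by the overall missing
fraction, (2) log2 transform, (3) per-sample centering/scaling across genes,
(4) per-gene centering/scaling anchored on the healthy controls.  Population
standard deviations (divide by n) are used throughout so the stated
invariants hold exactly; ``ddof`` is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import nan_euclidean_distances

from .io import ExpressionMatrix, ValidationError


@dataclass
class PreprocessConfig:
    """Tuning knobs of the missing-data policy and transforms.

    ``low_missing_frac``/``mid_missing_frac`` split datasets into the three
    missing-data regimes (<1%, 1-15%, >=15% overall missingness);
    ``gene_drop_frac`` is the per-gene missingness above which a gene is
    dropped in the two higher regimes; ``knn_k`` is the imputation
    neighborhood size.
    """

    low_missing_frac: float = 0.01
    mid_missing_frac: float = 0.15
    gene_drop_frac: float = 0.75
    knn_k: int = 5
    treat_zero_as_missing: bool = True
    already_log: bool = False
    ddof: int = 0  # population SD by default

    def __post_init__(self) -> None:
        if not 0 < self.low_missing_frac < self.mid_missing_frac < 1:
            raise ValidationError("need 0 < low_missing_frac < mid_missing_frac < 1")
        if not 0 < self.gene_drop_frac < 1:
            raise ValidationError("gene_drop_frac must be in (0, 1)")
        if self.knn_k < 1:
            raise ValidationError("knn_k must be >= 1")


def apply_missing_policy(
    X: ExpressionMatrix, cfg: PreprocessConfig | None = None
) -> ExpressionMatrix:
    """Filter/impute genes according to the overall missing fraction.

    * m < low: drop any gene with at least one missing value (no imputation).
    * low <= m < mid: drop genes missing in more than ``gene_drop_frac`` of
      samples, then KNN-impute the rest.
    * m >= mid: drop high-missing genes, leave remaining holes missing
      (downstream fits use pairwise deletion).
    """
    cfg = cfg or PreprocessConfig()
    vals = X.data
    m = float(vals.isna().to_numpy().mean()) if vals.size else 0.0
    if m == 0.0:
        return X
    if m < cfg.low_missing_frac:
        out = vals.loc[~vals.isna().any(axis=1)]
    else:
        gene_missing = vals.isna().mean(axis=1)
        out = vals.loc[gene_missing <= cfg.gene_drop_frac]
        if m < cfg.mid_missing_frac and out.isna().to_numpy().any():
            return knn_impute(ExpressionMatrix(out, X.scale), k=cfg.knn_k)
    if out.shape[0] == 0:
        raise ValidationError("missing-data policy dropped all genes")
    return ExpressionMatrix(out, X.scale)


def knn_impute(X: ExpressionMatrix, k: int = 5) -> ExpressionMatrix:
    """Impute each missing cell from the k nearest genes observed there.

    Gene-gene distance is Euclidean over the samples where both genes are
    observed, normalized per pair by the number of shared samples; for a hole
    at (gene g, sample s) the candidate neighbors are the genes observed at s
    that share at least one sample with g, and the imputed value is the plain
    mean of the k nearest candidates' values at s.  Observed values are never
    altered; genes with no usable neighbor stay missing with a warning.
    """
    vals = X.data.to_numpy(copy=True)
    mask = np.isnan(vals)
    if not mask.any():
        return X.copy()
    # nan_euclidean = sqrt(n_cols / n_shared * sum_shared (a-b)^2): a monotone
    # transform of the per-pair mean squared difference, so rankings match the
    # stated shared-sample-normalized distance.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dist = nan_euclidean_distances(vals, vals)
    np.fill_diagonal(dist, np.inf)
    out = vals.copy()
    orphan = []
    for g, s in zip(*np.nonzero(mask)):
        cand = ~mask[:, s] & np.isfinite(dist[g])
        if not cand.any():
            orphan.append(X.gene_ids[g])
            continue
        idx = np.nonzero(cand)[0]
        nearest = idx[np.argsort(dist[g, idx], kind="stable")[:k]]
        out[g, s] = vals[nearest, s].mean()
    if orphan:
        warnings.warn(
            f"{len(orphan)} cells left missing (no co-observed neighbors), "
            f"e.g. gene {orphan[0]!r}"
        )
    return ExpressionMatrix(
        pd.DataFrame(out, index=X.gene_ids, columns=X.sample_ids), X.scale
    )


def log2_transform(X: ExpressionMatrix, cfg: PreprocessConfig | None = None) -> ExpressionMatrix:
    """Log2-transform linear-scale values (no-op for already-log input)."""
    cfg = cfg or PreprocessConfig()
    if cfg.already_log or X.scale == "log2":
        return X.with_scale("log2") if X.scale == "linear" else X
    if X.scale != "linear":
        raise ValidationError(f"cannot log2-transform {X.scale} data")
    vals = X.data.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mn = np.nanmin(vals) if np.isfinite(vals).any() else 1.0
    if mn <= 0:
        raise ValidationError(
            "nonpositive observed values; zeros must be treated as missing "
            "before log transform"
        )
    return ExpressionMatrix(np.log2(X.data), "log2")


def standardize_samples(X: ExpressionMatrix, ddof: int = 0) -> ExpressionMatrix:
    """Center and scale each sample to mean 0 / SD 1 over its observed genes."""
    obs_counts = X.data.notna().sum(axis=0)
    if (obs_counts < 2).any():
        bad = X.sample_ids[obs_counts < 2][0]
        raise ValidationError(f"sample {bad!r} has fewer than 2 observed genes")
    mu = X.data.mean(axis=0)
    sd = X.data.std(axis=0, ddof=ddof)
    if (sd == 0).any():
        bad = X.sample_ids[(sd == 0).to_numpy()][0]
        raise ValidationError(f"sample {bad!r} has zero variance across genes")
    return ExpressionMatrix((X.data - mu) / sd, "standardized")


def standardize_genes_by_controls(
    X: ExpressionMatrix, control_sample_ids: list[str], ddof: int = 0
) -> ExpressionMatrix:
    """Center/scale each gene using mean and SD from control samples only.

    The control-derived transform is applied to all samples, so patient
    values are expressed as deviations from the healthy distribution.  Genes
    constant in controls are dropped with a warning.
    """
    controls = [c for c in control_sample_ids if c in X.sample_ids]
    if len(controls) < 3:
        raise ValidationError(
            "control-anchored standardization impossible: fewer than 3 controls"
        )
    ctrl = X.data[controls]
    n_obs = ctrl.notna().sum(axis=1)
    if (n_obs < 3).any():
        bad = X.gene_ids[n_obs < 3][0]
        raise ValidationError(f"gene {bad!r} observed in fewer than 3 controls")
    mu = ctrl.mean(axis=1)
    sd = ctrl.std(axis=1, ddof=ddof)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"dropping {int(flat.sum())} genes constant in controls")
    out = X.data.loc[~flat].sub(mu[~flat], axis=0).div(sd[~flat], axis=0)
    if out.shape[0] == 0:
        raise ValidationError("all genes constant in controls")
    return ExpressionMatrix(out, "standardized")


def preprocess_pipeline(
    X: ExpressionMatrix,
    control_sample_ids: list[str],
    cfg: PreprocessConfig | None = None,
) -> tuple[ExpressionMatrix, dict]:
    """Run steps 1-4 in order; returns the matrix plus a per-step report."""
    cfg = cfg or PreprocessConfig()
    report: dict = {"n_genes_in": X.n_genes, "n_samples": X.n_samples}
    if cfg.treat_zero_as_missing and not cfg.already_log and X.scale == "linear":
        X = ExpressionMatrix(X.data.mask(X.data == 0.0), X.scale)
    report["missing_frac"] = float(X.data.isna().to_numpy().mean())
    X = apply_missing_policy(X, cfg)
    report["n_genes_after_missing_policy"] = X.n_genes
    X = log2_transform(X, cfg)
    X = standardize_samples(X, ddof=cfg.ddof)
    X = standardize_genes_by_controls(X, control_sample_ids, ddof=cfg.ddof)
    report["n_genes_out"] = X.n_genes
    return X, report
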