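"""Hold-out and permutation schemes validating the predefined programs.

Approach 1 (inter-individual variation): genes are split into ten disjoint
folds; program levels are inferred with each fold's genes excluded, and each
held-out gene is then regressed on the inferred levels under three nested
models (joint, R-only, SI-only).  Per-gene R-squared values are compared to
a permutation null obtained by reshuffling the level vectors relative to the
held-out expression.

Approach 2 (inter-gene variation): per sample, the R-squared of the
expression profile on the predefined gene weights, with a null from
permuting the weights over genes.

Empirical p-values use the +1-corrected estimator and are never exactly 0.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    DEFAULT_MIN_OVERLAP,
    ExpressionMatrix,
    GeneWeightMap,
    ValidationError,
)
from .scoring import infer_program_levels

MODELS = ("joint", "R_only", "SI_only")
DEFAULT_CUTOFFS = (0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.5)


def _r2_columns(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """R^2 of OLS (with intercept) of each column of Y on predictor block X."""
    Xc = X - X.mean(axis=0)
    Q, _ = np.linalg.qr(Xc)
    Yc = Y - Y.mean(axis=0)
    num = ((Q.T @ Yc) ** 2).sum(axis=0)
    den = (Yc**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(den > 0, num / den, np.nan)
    return np.clip(r2, 0.0, 1.0)


def _f_pvalues(r2: np.ndarray, n: int, k: int) -> np.ndarray:
    """Overall regression F-test p for given R^2, n samples, k predictors."""
    dfd = n - 1 - k
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (r2 / k) / ((1.0 - r2) / dfd)
    return stats.f.sf(f, k, dfd)


def _complete_genes(Z: ExpressionMatrix) -> ExpressionMatrix:
    ok = Z.data.notna().all(axis=1)
    if not ok.all():
        warnings.warn(
            f"dropping {int((~ok).sum())} genes with missing values for the "
            "validation scheme"
        )
    return ExpressionMatrix(Z.data.loc[ok], Z.scale)


def _fold_partition(
    genes: pd.Index, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Random assignment of each gene to one of n disjoint folds."""
    fold = np.arange(len(genes)) % n_folds
    rng.shuffle(fold)
    return fold


def _fold_levels(
    Z: ExpressionMatrix,
    w_rt: GeneWeightMap,
    w_si: GeneWeightMap,
    fold: np.ndarray,
    k: int,
    min_overlap: int,
) -> np.ndarray:
    """Infer (S_R, S_SI) across samples with fold-k genes held out."""
    keep = Z.gene_ids[fold != k]
    if (
        len(keep.intersection(w_rt.gene_ids)) < min_overlap
        or len(keep.intersection(w_si.gene_ids)) < min_overlap
    ):
        raise ValidationError(
            f"fold {k} leaves fewer than {min_overlap} genes for level inference"
        )
    sub = ExpressionMatrix(Z.data.loc[keep], Z.scale)
    s_r = infer_program_levels(sub, w_rt, min_overlap)["s_program"]
    s_si = infer_program_levels(sub, w_si, min_overlap)["s_program"]
    return np.column_stack([s_r.to_numpy(), s_si.to_numpy()])


def heldout_variance(
    Z: ExpressionMatrix,
    w_rt: GeneWeightMap,
    w_si: GeneWeightMap,
    n_folds: int = 10,
    seed: int | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> pd.DataFrame:
    """Per-gene held-out explained variance under joint/R-only/SI-only models.

    Each gene is held out exactly once (the ten-repeat, 10%-without-
    replacement scheme read as one random partition into ten disjoint
    folds); its R^2 and regression F-test p come from the fold in which it
    was held out.
    """
    Z = _complete_genes(Z)
    rng = np.random.default_rng(seed)
    fold = _fold_partition(Z.gene_ids, n_folds, rng)
    n = Z.n_samples
    out = pd.DataFrame(
        index=Z.gene_ids,
        columns=["fold", "r2_joint", "r2_R_only", "r2_SI_only",
                 "p_joint", "p_R_only", "p_SI_only"],
        dtype=float,
    )
    for k in range(n_folds):
        S = _fold_levels(Z, w_rt, w_si, fold, k, min_overlap)
        held = fold == k
        Y = Z.values[held].T  # samples x held-out genes
        blocks = {"joint": S, "R_only": S[:, [0]], "SI_only": S[:, [1]]}
        for model, X in blocks.items():
            r2 = _r2_columns(Y, X)
            out.loc[held, f"r2_{model}"] = r2
            out.loc[held, f"p_{model}"] = _f_pvalues(r2, n, X.shape[1])
        out.loc[held, "fold"] = k
    out["fold"] = out["fold"].astype(int)
    return out


def permuted_null_heldout(
    Z: ExpressionMatrix,
    w_rt: GeneWeightMap,
    w_si: GeneWeightMap,
    n_folds: int = 10,
    n_perm: int = 100,
    seed: int | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> dict[str, np.ndarray]:
    """Null R^2 distributions from reshuffling levels against expression.

    Uses the same fold structure as :func:`heldout_variance` (same seed gives
    the matching partition); per permutation the sample order of the level
    matrix is shuffled relative to the held-out genes before the per-gene
    regressions, and null R^2 values are pooled across genes and
    permutations.  The identity permutation is excluded by construction.
    """
    if n_perm < 20:
        warnings.warn("n_perm < 20: empirical p resolution too coarse")
    Z = _complete_genes(Z)
    rng = np.random.default_rng(seed)
    fold = _fold_partition(Z.gene_ids, n_folds, rng)
    n = Z.n_samples
    null: dict[str, list[np.ndarray]] = {m: [] for m in MODELS}
    identity = np.arange(n)
    for k in range(n_folds):
        S = _fold_levels(Z, w_rt, w_si, fold, k, min_overlap)
        Y = Z.values[fold == k].T
        for _ in range(n_perm):
            perm = rng.permutation(n)
            while np.array_equal(perm, identity):  # pragma: no cover
                perm = rng.permutation(n)
            Sp = S[perm]
            null["joint"].append(_r2_columns(Y, Sp))
            null["R_only"].append(_r2_columns(Y, Sp[:, [0]]))
            null["SI_only"].append(_r2_columns(Y, Sp[:, [1]]))
    return {m: np.concatenate(v) for m, v in null.items()}


def empirical_pvalues(real: np.ndarray, null: np.ndarray) -> np.ndarray:
    """+1-corrected permutation p: (1 + #{null >= real}) / (1 + N_null)."""
    null = np.sort(np.asarray(null))
    n = len(null)
    if n == 0:
        raise ValidationError("empty null distribution")
    n_ge = n - np.searchsorted(null, np.asarray(real), side="left")
    return (1.0 + n_ge) / (1.0 + n)


def percent_significant(
    real: np.ndarray, null: np.ndarray, alpha: float = 0.05
) -> float:
    """Percentage of genes whose empirical (permutation) p is below alpha."""
    p = empirical_pvalues(real, null)
    return 100.0 * float(np.mean(p < alpha))


def tpr_fpr_f1(
    real_r2: np.ndarray,
    perm_r2: np.ndarray,
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
) -> pd.DataFrame:
    """TPR/FPR/precision/recall/F1 at R^2 cutoffs for matched real/permuted runs.

    TPR(c) is the fraction of real genes with R^2 > c (a lower bound on the
    true positive rate), FPR(c) the same fraction in the permuted copy;
    precision = TPR / (TPR + FPR) under the equal-set-size convention of one
    matched permuted run.
    """
    real_r2 = np.asarray(real_r2, dtype=float)
    perm_r2 = np.asarray(perm_r2, dtype=float)
    rows = []
    for c in cutoffs:
        tpr = float(np.mean(real_r2 > c))
        fpr = float(np.mean(perm_r2 > c))
        precision = tpr / (tpr + fpr) if tpr + fpr > 0 else 0.0
        recall = tpr
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        rows.append(
            {"cutoff": c, "TPR": tpr, "FPR": fpr,
             "precision": precision, "recall": recall, "F1": f1}
        )
    return pd.DataFrame(rows)


def intergene_variation(
    Z: ExpressionMatrix,
    W: GeneWeightMap,
    n_perm: int = 200,
    seed: int | None = None,
    alpha: float = 0.05,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[pd.DataFrame, float]:
    """Per-sample R^2 of expression on the gene weights, with a weight-permutation null.

    Returns the per-sample table (r2, empirical_p) and the percentage of
    samples with empirical p < alpha.
    """
    from .io import align_genes

    Zs, Ws = align_genes(_complete_genes(Z), W, min_overlap)
    rng = np.random.default_rng(seed)
    V = np.column_stack([Ws.confounder_weights, Ws.program_weights])
    Y = Zs.values  # genes x samples; columns are the regression targets
    real = _r2_columns(Y, V)
    null = np.empty((n_perm, Zs.n_samples))
    for i in range(n_perm):
        null[i] = _r2_columns(Y, V[rng.permutation(len(V))])
    emp_p = (1.0 + (null >= real[None, :]).sum(axis=0)) / (1.0 + n_perm)
    table = pd.DataFrame({"r2": real, "empirical_p": emp_p}, index=Zs.sample_ids)
    return table, 100.0 * float(np.mean(emp_p < alpha))
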