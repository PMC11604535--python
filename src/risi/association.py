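"""Associating R/SI levels with phenotypes, proteins and marker genes.

Variance-explained analyses regress a phenotype on the inferred levels
(SI-only, R-only, or the joint linear combination) and calibrate the
R-squared against a permutation null; 2D correlation maps place every
feature by its correlation with SI (x) and R (y); balance markers are genes
whose expression tracks the R/SI-balance score consistently across cohorts,
tested for pathway enrichment with the hypergeometric test and
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, ValidationError
from .validation import _r2_columns

ASSOC_MODELS = ("SI_only", "R_only", "joint")


def _design(levels: pd.DataFrame, model: str, covariates: pd.DataFrame | None):
    cols = {"SI_only": ["z_SI"], "R_only": ["z_R"], "joint": ["z_R", "z_SI"]}[model]
    X = levels[cols].to_numpy(dtype=float)
    if covariates is not None:
        X = np.column_stack([X, covariates.loc[levels.index].to_numpy(dtype=float)])
    return X


def variance_explained(
    phenotype: pd.Series,
    levels: pd.DataFrame,
    model: str = "joint",
    n_perm: int = 1000,
    seed: int | None = None,
    covariates: pd.DataFrame | None = None,
    min_n: int = 20,
) -> dict:
    """R^2 of a phenotype on the program levels, with a permutation p.

    The phenotype is permuted across samples; empirical p is the
    +1-corrected fraction of permutations with R^2 at least the real one.
    Optional covariate columns give the confounder-adjusted variant.
    """
    if model not in ASSOC_MODELS:
        raise ValidationError(f"unknown model {model!r}")
    shared = phenotype.dropna().index.intersection(levels.index)
    if len(shared) < min_n:
        raise ValidationError(
            f"only {len(shared)} samples with phenotype and levels (< {min_n})"
        )
    y = phenotype.loc[shared].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValidationError("constant phenotype")
    X = _design(levels.loc[shared], model, covariates)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(len(y)) for _ in range(n_perm)])
    # y is permuted against a fixed design: project all permuted copies at once
    Y = np.column_stack([y] + [y[p] for p in perms])
    r2 = _r2_columns(Y, X)
    real, null = float(r2[0]), r2[1:]
    emp_p = (1.0 + float((null >= real).sum())) / (1.0 + n_perm)
    return {"model": model, "r2": real, "empirical_p": emp_p, "n": len(y)}


def variance_explained_table(
    phenotypes: pd.DataFrame,
    levels: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    **kw,
) -> pd.DataFrame:
    """variance_explained for every phenotype column x model."""
    rows = []
    for i, col in enumerate(phenotypes.columns):
        for model in ASSOC_MODELS:
            try:
                res = variance_explained(
                    phenotypes[col], levels, model,
                    n_perm=n_perm,
                    seed=None if seed is None else seed + i,
                    **kw,
                )
            except ValidationError as exc:
                warnings.warn(f"phenotype {col!r}: {exc}")
                continue
            rows.append({"phenotype": col, **res})
    return pd.DataFrame(rows)


def correlation_map(
    feature_table: pd.DataFrame, levels: pd.DataFrame, min_n: int = 10
) -> pd.DataFrame:
    """Per-feature Pearson correlations with z_SI and z_R (the 2D map).

    ``feature_table`` is samples x features (proteins, genes, phenotypes);
    pairwise-complete samples are used; features with fewer than ``min_n``
    observations (or constant) are skipped with a warning.
    """
    shared = feature_table.index.intersection(levels.index)
    feats = feature_table.loc[shared]
    lev = levels.loc[shared]
    out = {}
    skipped = []
    for f in feats.columns:
        obs = feats[f].notna()
        if obs.sum() < min_n or feats.loc[obs, f].std() == 0:
            skipped.append(f)
            continue
        x = feats.loc[obs, f].to_numpy(dtype=float)
        out[f] = {
            "r_SI": float(np.corrcoef(x, lev.loc[obs, "z_SI"])[0, 1]),
            "r_R": float(np.corrcoef(x, lev.loc[obs, "z_R"])[0, 1]),
        }
    if skipped:
        warnings.warn(f"skipped {len(skipped)} features, e.g. {skipped[0]!r}")
    return pd.DataFrame.from_dict(out, orient="index")


def rank_balance_markers(
    cohorts: dict[str, tuple[ExpressionMatrix, pd.DataFrame]],
    monocyte_cohort_id: str,
    good_thresh: float = 0.6,
    impaired_thresh: float = -0.45,
    top_n: int = 300,
) -> pd.DataFrame:
    """Rank genes as markers of the R/SI-balance score across cohorts.

    Per cohort, each gene's Pearson correlation with the balance score; the
    unweighted mean across cohorts ranks the genes.  Genes with mean r above
    ``good_thresh`` (below ``impaired_thresh``) are selected as good-balance
    (impaired-balance) markers, and within each selected set the ``top_n``
    markers are chosen by the correlation magnitude in the monocyte cohort.
    """
    if len(cohorts) < 2:
        raise ValidationError("need >= 2 cohorts")
    if monocyte_cohort_id not in cohorts:
        raise ValidationError(f"monocyte cohort {monocyte_cohort_id!r} not supplied")
    per_cohort = {}
    for cid, (X, levels) in sorted(cohorts.items()):
        bal = levels.loc[X.sample_ids, "balance"].to_numpy(dtype=float)
        vals = X.values
        bal_c = bal - bal.mean()
        v_c = vals - np.nanmean(vals, axis=1, keepdims=True)
        num = np.nansum(v_c * bal_c[None, :], axis=1)
        den = np.sqrt(np.nansum(v_c**2, axis=1) * (bal_c**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            per_cohort[cid] = pd.Series(np.where(den > 0, num / den, np.nan),
                                        index=X.gene_ids)
    table = pd.DataFrame(per_cohort)
    out = pd.DataFrame(index=table.index)
    for cid in table.columns:
        out[f"r_{cid}"] = table[cid]
    out["n_cohorts"] = table.notna().sum(axis=1)
    out["mean_r_balance"] = table.mean(axis=1)
    out["selected_good"] = out["mean_r_balance"] > good_thresh
    out["selected_impaired"] = out["mean_r_balance"] < impaired_thresh
    mono = table[monocyte_cohort_id].abs()
    for flag, top_flag in (
        ("selected_good", "top_good"),
        ("selected_impaired", "top_impaired"),
    ):
        sel = out.index[out[flag]]
        top = mono.loc[sel].sort_values(ascending=False).index[:top_n]
        out[top_flag] = out.index.isin(top)
    return out


def hypergeom_enrich(
    markers: set[str] | list[str],
    collections: dict[str, set[str] | list[str]],
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a marker set, BH-adjusted.

    Each named gene set is intersected with the universe; p is
    P(overlap >= observed) under sampling |markers| genes from the universe;
    q values are Benjamini-Hochberg across all tested sets.
    """
    universe = set(universe)
    markers = set(markers)
    if not universe or not markers:
        raise ValidationError("empty universe or marker set")
    if not markers <= universe:
        raise ValidationError("markers must be a subset of the universe")
    N, n = len(universe), len(markers)
    rows = []
    for name, genes in collections.items():
        K = len(set(genes) & universe)
        k = len(set(genes) & markers)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "set_size": K, "overlap": k, "p": p})
    out = pd.DataFrame(rows).set_index("set")
    out["q_BH"] = stats.false_discovery_control(out["p"], method="bh")
    return out


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene-set collections in GMT format (name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets
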