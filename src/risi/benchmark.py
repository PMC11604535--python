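"""Benchmarking candidate transcriptional programs.

Candidate programs (plain genesets or gene-weight pairs) are scored by
(1) their disease-vs-healthy response, a signed two-sample rank statistic,
and (2) how well their cross-dataset covariation ranking retrieves labeled
sepsis/infection datasets, summarized by the covariation-F1 score.  The
covariation statistic here — mean pairwise correlation among program genes,
z-scored against size-matched random genesets — is a local stand-in for a
co-expression search engine; externally computed rankings can be supplied
verbatim to the F1 layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneWeightMap, ValidationError
from .scoring import infer_program_levels


@dataclass
class ProgramDef:
    """A candidate program: a geneset or a weighted program pair."""

    name: str
    mode: str  # "geneset" | "gene_weights"
    genes: list[str] | None = None
    weights: GeneWeightMap | None = None
    top_n_query: int = 100  # geneset size when a weights program is used as a query

    def __post_init__(self) -> None:
        if self.mode == "geneset":
            if not self.genes or len(self.genes) < 10:
                raise ValidationError(
                    f"geneset program {self.name!r} needs >= 10 genes"
                )
        elif self.mode == "gene_weights":
            if self.weights is None:
                raise ValidationError(
                    f"gene_weights program {self.name!r} needs a weight map"
                )
        else:
            raise ValidationError(f"unknown program mode {self.mode!r}")

    def query_genes(self) -> list[str]:
        """Geneset used for covariation queries (top-|weight| genes for weights mode)."""
        if self.mode == "geneset":
            return list(self.genes)
        w = self.weights.table["program"].abs().sort_values(ascending=False)
        return list(w.index[: self.top_n_query])


def program_level_simple(program: ProgramDef, Z: ExpressionMatrix) -> pd.Series:
    """Per-sample program level: geneset mean, or the fitted program coefficient."""
    if program.mode == "gene_weights":
        return infer_program_levels(Z, program.weights)["s_program"].rename(
            program.name
        )
    present = Z.gene_ids.intersection(program.genes)
    if len(present) < 5:
        raise ValidationError(
            f"program {program.name!r}: only {len(present)} genes present (< 5)"
        )
    return Z.data.loc[present].mean(axis=0, skipna=True).rename(program.name)


def response_score(levels: pd.Series, labels: pd.Series) -> float:
    """Signed standardized rank-sum statistic, disease vs healthy.

    Mann-Whitney U of the disease group converted to a (tie-corrected)
    normal z; positive when disease levels tend to exceed healthy levels.
    The disease-vs-healthy comparison is unpaired, so the two-sample
    rank-sum statistic is used.
    """
    labels = labels.loc[levels.index]
    disease = levels[labels != "healthy"].to_numpy()
    healthy = levels[labels == "healthy"].to_numpy()
    if len(disease) < 3 or len(healthy) < 3:
        raise ValidationError("need >= 3 disease and >= 3 healthy samples")
    n1, n2 = len(disease), len(healthy)
    u = stats.mannwhitneyu(disease, healthy, alternative="two-sided").statistic
    mu = n1 * n2 / 2.0
    # tie-corrected variance of U
    pooled = np.concatenate([disease, healthy])
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    sigma = np.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie_term))
    if sigma == 0:
        return 0.0
    return float((u - mu) / sigma)


def dataset_covariation_rank(
    program: ProgramDef,
    datasets: dict[str, ExpressionMatrix],
    labels: dict[str, str] | None = None,
    n_random: int = 50,
    seed: int | None = None,
    min_genes: int = 5,
) -> pd.DataFrame:
    """Rank datasets by the covariation of the program's genes.

    Per dataset: mean pairwise Pearson correlation among the program genes,
    z-scored against ``n_random`` size-matched random genesets drawn from the
    same dataset.  Datasets with fewer than ``min_genes`` program genes get a
    missing statistic and are ranked last.  Ties break by stable input order.
    Returns a DataFrame (index dataset_id): ``covariation_z``, ``rank``,
    ``label``, ``tied``.
    """
    if len(datasets) < 2:
        raise ValidationError("need >= 2 datasets to rank")
    query = program.query_genes()
    if len(query) < min_genes:
        raise ValidationError(
            f"program {program.name!r} has fewer than {min_genes} query genes"
        )
    zs = {}
    for ds_id, X in datasets.items():
        present = X.gene_ids.intersection(query)
        if len(present) < min_genes:
            warnings.warn(
                f"dataset {ds_id!r}: only {len(present)} program genes; "
                "ranked last with missing statistic"
            )
            zs[ds_id] = np.nan
            continue
        # per-dataset rng: identical datasets get identical statistics
        zs[ds_id] = _covariation_z(X, present, n_random, np.random.default_rng(seed))
    out = pd.DataFrame({"covariation_z": pd.Series(zs)})
    order = out["covariation_z"].rank(
        ascending=False, method="first", na_option="bottom"
    )
    out["rank"] = order.astype(int)
    dup = out["covariation_z"].duplicated(keep=False) & out["covariation_z"].notna()
    out["tied"] = dup
    out["label"] = pd.Series(labels) if labels else "other"
    return out


def _mean_pairwise_corr(vals: np.ndarray) -> float:
    """Mean off-diagonal Pearson correlation among rows (genes)."""
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(vals)
    m = len(vals)
    off = c[~np.eye(m, dtype=bool)]
    return float(np.nanmean(off))


def _covariation_z(
    X: ExpressionMatrix, genes: pd.Index, n_random: int, rng: np.random.Generator
) -> float:
    vals = X.data.loc[genes].to_numpy()
    real = _mean_pairwise_corr(vals)
    m = len(genes)
    null = np.empty(n_random)
    all_vals = X.values
    for i in range(n_random):
        pick = rng.choice(X.n_genes, size=m, replace=False)
        null[i] = _mean_pairwise_corr(all_vals[pick])
    sd = null.std(ddof=0)
    if sd == 0:
        return 0.0
    return (real - null.mean()) / sd


def covariation_f1(ranking: pd.DataFrame, positive_class: str) -> float:
    """Mean F1 over cutoffs at each positive dataset's rank.

    For each positive dataset's rank c, predicted positives are the datasets
    ranked <= c; the score is the mean of the F1 values over the positives'
    cutoffs.  Measures how well the covariation ranking retrieves the
    labeled dataset class.
    """
    ranks = ranking["rank"].to_numpy()
    positive = (ranking["label"] == positive_class).to_numpy()
    n_pos = int(positive.sum())
    if n_pos < 1:
        raise ValidationError(f"no datasets labeled {positive_class!r}")
    f1s = []
    for c in ranks[positive]:
        predicted = ranks <= c
        tp = int((predicted & positive).sum())
        precision = tp / predicted.sum()
        recall = tp / n_pos
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        f1s.append(f1)
    return float(np.mean(f1s))


def benchmark_programs(
    programs: list[ProgramDef],
    datasets: dict[str, ExpressionMatrix],
    labels: dict[str, str],
    response_labels: dict[str, pd.Series] | None = None,
    n_random: int = 50,
    seed: int | None = None,
) -> pd.DataFrame:
    """Score every candidate program on covariation retrieval (and response).

    Returns one row per program: covariation-F1 for the sepsis and infection
    dataset classes, plus per-dataset response z-scores when sample-level
    condition labels are supplied.
    """
    rows = []
    for prog in programs:
        ranking = dataset_covariation_rank(
            prog, datasets, labels, n_random=n_random, seed=seed
        )
        row: dict = {"program": prog.name}
        for cls in ("sepsis", "infection"):
            if (ranking["label"] == cls).any():
                row[f"covariation_{cls}_f1"] = covariation_f1(ranking, cls)
        if response_labels:
            for ds_id, lab in response_labels.items():
                lev = program_level_simple(prog, datasets[ds_id])
                row[f"response_{ds_id}"] = response_score(lev, lab)
        rows.append(row)
    return pd.DataFrame(rows).set_index("program")
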