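"""Domain containers and file I/O shared by every analysis stage.

Expression data live in a genes x samples :class:`ExpressionMatrix` backed by
a pandas DataFrame with ``NaN`` as the single in-memory missing marker.  Gene
identifiers are opaque, case-sensitive strings; any symbol/probe/Ensembl
conversion is the caller's responsibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

VALID_SCALES = ("linear", "log2", "standardized")
#: allowed scale transitions: linear -> log2 -> standardized
_SCALE_ORDER = {s: i for i, s in enumerate(VALID_SCALES)}

DEFAULT_MIN_OVERLAP = 50


class ParseError(ValueError):
    """Malformed input file (bad header, duplicate ids, non-numeric cells)."""


class ValidationError(ValueError):
    """A domain invariant was violated."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dups = s[s.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes x samples real matrix with an explicit missing marker (NaN).

    Parameters
    ----------
    data
        DataFrame indexed by gene id, columns are sample ids, float values.
    scale
        One of ``linear``, ``log2``, ``standardized``.
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}")
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def with_scale(self, scale: str) -> "ExpressionMatrix":
        """Return self re-tagged with a later scale (transitions are one-way)."""
        if _SCALE_ORDER[scale] < _SCALE_ORDER[self.scale]:
            raise ValidationError(
                f"scale transition {self.scale} -> {scale} not allowed"
            )
        return ExpressionMatrix(self.data, scale)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), self.scale)


@dataclass
class GeneWeightMap:
    """Predefined per-gene weights for one program pair.

    Each pair couples a program of interest with its confounder: the
    resistance pair (confounder T, program R) and the systemic-inflammation
    pair (confounder IM1, program SI).  Weights are external inputs, never
    re-derived here.
    """

    table: pd.DataFrame  # index gene_id; columns: confounder, program
    pair_name: str  # "R_T" or "SI_IM1"
    min_genes: int = 50

    def __post_init__(self) -> None:
        if self.pair_name not in ("R_T", "SI_IM1"):
            raise ValidationError(f"unknown pair name {self.pair_name!r}")
        if list(self.table.columns) != ["confounder", "program"]:
            self.table = self.table.rename(
                columns=dict(zip(self.table.columns, ["confounder", "program"]))
            )
        _check_unique(self.table.index, "weight-map genes")
        if len(self.table) < self.min_genes:
            raise ValidationError(
                f"too few genes in weight map ({len(self.table)} < {self.min_genes})"
            )
        if not np.isfinite(self.table.to_numpy()).all():
            raise ValidationError("non-finite weights in weight map")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def confounder_weights(self) -> np.ndarray:
        return self.table["confounder"].to_numpy()

    @property
    def program_weights(self) -> np.ndarray:
        return self.table["program"].to_numpy()

    def subset(self, genes: pd.Index) -> "GeneWeightMap":
        return GeneWeightMap(self.table.loc[genes], self.pair_name, self.min_genes)


CONDITIONS = ("healthy", "moderate_infection", "sepsis", "other")


@dataclass
class SampleTable:
    """Per-sample metadata: condition labels plus optional covariates."""

    frame: pd.DataFrame  # index sample_id; columns: condition [, dataset_id, age, sex, timepoint]

    def __post_init__(self) -> None:
        _check_unique(self.frame.index, "sample ids")
        if "condition" not in self.frame.columns:
            raise ValidationError("sample table needs a 'condition' column")
        bad = set(self.frame["condition"]) - set(CONDITIONS)
        if bad:
            raise ValidationError(f"unknown conditions {sorted(bad)}")
        if self.frame["condition"].isna().any():
            raise ValidationError("condition missing for some samples")

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index

    def ids_where(self, condition: str) -> list[str]:
        return list(self.frame.index[self.frame["condition"] == condition])

    @property
    def control_ids(self) -> list[str]:
        return self.ids_where("healthy")


@dataclass
class HomologMap:
    """Strictly one-to-one source -> target gene mapping (e.g. mouse -> human)."""

    pairs: pd.Series  # index source gene, value target gene

    def __post_init__(self) -> None:
        if isinstance(self.pairs, Mapping):
            self.pairs = pd.Series(self.pairs)
        _check_unique(self.pairs.index, "homolog source genes")
        _check_unique(self.pairs.values, "homolog target genes")


@dataclass
class CohortBundle:
    """Expression + metadata (+ optional proteins and survival) for one cohort."""

    expression: ExpressionMatrix
    samples: SampleTable
    proteins: pd.DataFrame | None = None  # samples x proteins
    survival: pd.DataFrame | None = None  # index sample_id: time_days, event [, age, sex]

    def __post_init__(self) -> None:
        ids = set(self.expression.sample_ids)
        if set(self.samples.sample_ids) != ids:
            raise ValidationError("sample table ids differ from expression samples")
        for name, tab in (("proteins", self.proteins), ("survival", self.survival)):
            if tab is not None and not set(tab.index) <= ids:
                raise ValidationError(f"{name} table has unknown sample ids")


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(
    path: str | Path,
    format: str = "tsv",
    scale_hint: str = "linear",
    features_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV/CSV (genes x samples) or MTX triplet.

    For dense text formats the first column holds gene ids and the header row
    holds sample ids; empty cells are missing.  When ``scale_hint`` is
    ``linear``, zero values are additionally flagged missing (zero counts are
    unmeasured on a linear scale); on log scales zeros are meaningful and kept.
    MTX triplets (cells as matrix columns after transposition) are loaded
    densely with structural zeros kept as zeros.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ParseError(f"{path}: duplicated gene rows {dup[:5]}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise ParseError(f"{path}: duplicated sample columns {dup[:5]}")
        try:
            df = df.astype(float)
        except (TypeError, ValueError) as exc:
            bad = df.apply(pd.to_numeric, errors="coerce")
            cells = np.argwhere(bad.isna().to_numpy() & df.notna().to_numpy())
            loc = ""
            if len(cells):
                g, s = cells[0]
                loc = f" (gene {df.index[g]!r}, sample {df.columns[s]!r})"
            raise ParseError(f"{path}: non-numeric cell{loc}") from exc
    elif format == "mtx_triplet":
        if features_path is None or barcodes_path is None:
            raise ParseError("mtx_triplet needs matrix, features and barcodes files")
        mat = scipy.io.mmread(path)
        genes = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str)
        cells = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        if dense.shape != (len(genes), len(cells)):
            raise ParseError(
                f"mtx shape {dense.shape} does not match "
                f"{len(genes)} features x {len(cells)} barcodes"
            )
        df = pd.DataFrame(dense, index=genes, columns=cells)
        # structural zeros in counts are true zeros, not missing
        return ExpressionMatrix(df, scale_hint)
    else:
        raise ParseError(f"unknown format {format!r}")

    if scale_hint == "linear":
        df = df.mask(df == 0.0)
    return ExpressionMatrix(df, scale_hint)


def write_expression(X: ExpressionMatrix, path: str | Path, fmt: str = "%.6f") -> None:
    """Write genes x samples TSV; missing cells become empty fields."""
    X.data.to_csv(path, sep="\t", float_format=fmt, na_rep="")


def read_gene_weights(path: str | Path, pair_name: str) -> GeneWeightMap:
    """Read a 3-column TSV: gene id, confounder weight, program weight."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] != 2:
        raise ParseError(
            f"{path}: expected gene + 2 weight columns, got {df.shape[1] + 1}"
        )
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric weight") from exc
    df.columns = ["confounder", "program"]
    return GeneWeightMap(df, pair_name)


def write_gene_weights(W: GeneWeightMap, path: str | Path) -> None:
    W.table.to_csv(path, sep="\t")


def read_sample_table(path: str | Path) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep="\t", index_col=0))


# ---------------------------------------------------------------------------
# gene handling


def map_homologs(matrix: ExpressionMatrix, hmap: HomologMap) -> ExpressionMatrix:
    """Rename genes via a one-to-one homolog map, dropping unmapped genes."""
    keep = matrix.gene_ids.intersection(hmap.pairs.index)
    if len(keep) == 0:
        warnings.warn("homolog map shares no genes with the matrix")
    out = matrix.data.loc[keep].rename(index=hmap.pairs.to_dict())
    return ExpressionMatrix(out, matrix.scale)


def align_genes(
    matrix: ExpressionMatrix,
    weights: GeneWeightMap,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[ExpressionMatrix, GeneWeightMap]:
    """Restrict matrix and weight map to their gene intersection, same order.

    The weight maps cap the usable gene set; fewer genes may actually have
    been measured.  Inference on fewer than ``min_overlap`` shared genes is
    refused as unstable.
    """
    shared = matrix.gene_ids.intersection(weights.gene_ids)
    if len(shared) < min_overlap:
        raise ValidationError(
            f"only {len(shared)} genes shared between matrix and "
            f"{weights.pair_name} weights (< {min_overlap})"
        )
    return (
        ExpressionMatrix(matrix.data.loc[shared], matrix.scale),
        weights.subset(shared),
    )
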