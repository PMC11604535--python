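"""Per-cell R/SI scoring and patient-level response statistics.

Single cells are scored exactly like bulk samples — each cell's normalized,
standardized profile is regressed on the predefined weight pairs — and a
patient's "R (or SI) response" in a cell subpopulation is the signed log10
Welch t-test p-value comparing that patient's cells to all pooled control
cells of the same subpopulation (positive = increased program level).

Per-cell preprocessing deliberately differs from the bulk pipeline: dropout
zeros are kept as zeros (not missing), counts are depth-normalized
(counts-per-10k, optional) and log2(1+x)-transformed, each cell is centered
and scaled across genes, and gene-level standardization is anchored on the
control cells of the same subpopulation to avoid composition artifacts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import DEFAULT_MIN_OVERLAP, ExpressionMatrix, GeneWeightMap, ValidationError
from .scoring import infer_program_levels

P_FLOOR = 1e-300  # caps |signed log10 p| at 300

REQUIRED_ANNOTATION = ("patient_id", "group", "subpopulation")


def _check_annotation(annotation: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_ANNOTATION if c not in annotation.columns]
    if missing:
        raise ValidationError(f"cell annotation missing columns {missing}")


def normalize_cells(
    counts: ExpressionMatrix, cp10k: bool = True, target: float = 1e4
) -> ExpressionMatrix:
    """Depth-normalize raw counts and log2(1+x)-transform (zeros stay zeros)."""
    vals = counts.data.to_numpy(dtype=float)
    if cp10k:
        depth = vals.sum(axis=0)
        if (depth == 0).any():
            raise ValidationError("cells with zero total counts cannot be normalized")
        vals = vals / depth * target
    return ExpressionMatrix(
        pd.DataFrame(
            np.log2(1.0 + vals), index=counts.gene_ids, columns=counts.sample_ids
        ),
        "log2",
    )


def _standardize_columns(df: pd.DataFrame) -> pd.DataFrame:
    mu = df.mean(axis=0)
    sd = df.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValidationError("cells with zero variance across genes")
    return (df - mu) / sd


def per_cell_levels(
    cells: ExpressionMatrix,
    w_rt: GeneWeightMap,
    w_si: GeneWeightMap,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> pd.DataFrame:
    """Per-cell s_R and s_SI from a standardized cell matrix (genes x cells)."""
    rt = infer_program_levels(cells, w_rt, min_overlap)
    si = infer_program_levels(cells, w_si, min_overlap)
    return pd.DataFrame({"s_R": rt["s_program"], "s_SI": si["s_program"]})


def single_cell_pipeline(
    counts: ExpressionMatrix,
    annotation: pd.DataFrame,
    w_rt: GeneWeightMap,
    w_si: GeneWeightMap,
    control_group: str = "control",
    cp10k: bool = True,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> pd.DataFrame:
    """Normalize, standardize and score every cell, per subpopulation.

    Gene standardization uses the control cells of the same subpopulation as
    the reference population.  Returns per-cell levels joined with the
    annotation.
    """
    _check_annotation(annotation)
    if not set(annotation.index) <= set(counts.sample_ids):
        raise ValidationError("annotation contains unknown cell ids")
    logged = normalize_cells(counts, cp10k=cp10k)
    results = []
    for sub, cells_ann in annotation.groupby("subpopulation"):
        sub_df = logged.data[cells_ann.index]
        sub_df = _standardize_columns(sub_df)
        ctrl_cells = cells_ann.index[cells_ann["group"] == control_group]
        if len(ctrl_cells) < 3:
            raise ValidationError(
                f"subpopulation {sub!r} has fewer than 3 control cells"
            )
        mu = sub_df[ctrl_cells].mean(axis=1)
        sd = sub_df[ctrl_cells].std(axis=1, ddof=0)
        keep = sd > 0
        zed = sub_df.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
        Z = ExpressionMatrix(zed, "standardized")
        levels = per_cell_levels(Z, w_rt, w_si, min_overlap)
        results.append(levels.join(cells_ann))
    return pd.concat(results)


def patient_response(
    cell_levels: pd.DataFrame,
    patient_id: str,
    subpopulation: str,
    program: str,
    control_group: str = "control",
    min_cells: int = 10,
) -> dict:
    """Signed log10 Welch-t p for one patient x subpopulation x program.

    Compares the patient's per-cell levels in the subpopulation against all
    pooled control cells of that subpopulation; the sign is positive when
    the patient mean exceeds the control mean.  Scores are deterministic (no
    RNG) and capped at |300| by the double-precision p floor.
    """
    col = f"s_{program}"
    if col not in cell_levels.columns:
        raise ValidationError(f"unknown program {program!r}")
    sub = cell_levels[cell_levels["subpopulation"] == subpopulation]
    pat = sub.loc[sub["patient_id"] == patient_id, col].to_numpy()
    ctrl = sub.loc[sub["group"] == control_group, col].to_numpy()
    base = {
        "patient_id": patient_id,
        "subpopulation": subpopulation,
        "program": program,
        "n_cells_patient": len(pat),
        "n_cells_controls": len(ctrl),
    }
    if len(pat) < min_cells or len(ctrl) < min_cells:
        return {**base, "signed_log10_p": np.nan, "p": np.nan,
                "reason": "too few cells"}
    t = stats.ttest_ind(pat, ctrl, equal_var=False)
    p = max(float(t.pvalue), P_FLOOR)
    sign = 1.0 if pat.mean() > ctrl.mean() else -1.0
    return {**base, "signed_log10_p": sign * -np.log10(p), "p": p, "reason": ""}


def all_patient_responses(
    cell_levels: pd.DataFrame,
    control_group: str = "control",
    programs: tuple[str, ...] = ("R", "SI"),
    min_cells: int = 10,
) -> pd.DataFrame:
    """Response scores for every patient x subpopulation x program."""
    rows = []
    patients = cell_levels.loc[
        cell_levels["group"] != control_group, "patient_id"
    ].unique()
    for sub in cell_levels["subpopulation"].unique():
        for pid in patients:
            for prog in programs:
                rows.append(
                    patient_response(
                        cell_levels, pid, sub, prog,
                        control_group=control_group, min_cells=min_cells,
                    )
                )
    return pd.DataFrame(rows)


def response_summary(
    scores: pd.DataFrame,
    alpha: float = 0.05,
    cell_type_of: dict[str, str] | None = None,
) -> pd.Series:
    """Per-cell-type percentage of patients with a significant response.

    A patient counts as responsive for a cell type when any of its
    subpopulation x program scores has p < alpha.  ``cell_type_of`` maps
    subpopulation labels to cell types; by default the trailing digits of
    the subpopulation label are stripped (MS1..MS4 -> MS).
    """
    if scores.empty:
        import warnings

        warnings.warn("empty score list; response summary is 0%")
        return pd.Series(dtype=float)
    scores = scores.copy()
    if cell_type_of is None:
        scores["cell_type"] = scores["subpopulation"].str.replace(
            r"\d+$", "", regex=True
        )
    else:
        scores["cell_type"] = scores["subpopulation"].map(cell_type_of)
    out = {}
    for ct, grp in scores.groupby("cell_type"):
        hits = grp.assign(sig=grp["p"] < alpha).groupby("patient_id")["sig"].any()
        out[ct] = 100.0 * float(hits.mean())
    return pd.Series(out)
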