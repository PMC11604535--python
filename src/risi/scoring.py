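"""Program-level inference, the R/SI-balance score, and protein-based levels.

The central operation regresses each sample's standardized expression
profile Z_i on a two-predictor design built from predefined gene weights,

    Z_i = b_i + s_conf,i * V_conf + s_prog,i * V_prog ,

fitted by ordinary least squares separately for the resistance pair
(confounder T, program R) and the systemic-inflammation pair (confounder
IM1, program SI).  The program coefficients s_R and s_SI are the per-sample
levels; after control-anchored standardization their difference z_R - z_SI
is the R/SI-balance score (negative = impaired balance, the sepsis
fingerprint).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import (
    DEFAULT_MIN_OVERLAP,
    ExpressionMatrix,
    GeneWeightMap,
    ValidationError,
    align_genes,
)

MAX_CONDITION = 1e8


def _ols_levels(
    Z: np.ndarray, design: np.ndarray, min_overlap: int, pair_name: str
) -> np.ndarray:
    """OLS coefficients of each column of Z (genes x samples) on the design.

    Missing genes are excluded per sample (pairwise deletion).  Returns an
    array (n_samples, 3): intercept, confounder level, program level.
    """
    cond = np.linalg.cond(design[~np.isnan(design).any(axis=1)])
    if cond > MAX_CONDITION:
        raise ValidationError(
            f"collinear weight vectors for pair {pair_name} "
            f"(condition number {cond:.3g})"
        )
    n_samples = Z.shape[1]
    coefs = np.empty((n_samples, 3))
    missing = np.isnan(Z)
    if not missing.any():
        coefs[:] = np.linalg.lstsq(design, Z, rcond=None)[0].T
        return coefs
    complete = ~missing.any(axis=0)
    if complete.any():
        coefs[complete] = np.linalg.lstsq(design, Z[:, complete], rcond=None)[0].T
    for j in np.nonzero(~complete)[0]:
        obs = ~missing[:, j]
        if obs.sum() < min_overlap:
            raise ValidationError(
                f"sample column {j} has only {int(obs.sum())} observed genes "
                f"shared with the {pair_name} weights (< {min_overlap})"
            )
        sub = design[obs]
        cond = np.linalg.cond(sub)
        if cond > MAX_CONDITION:
            raise ValidationError(
                f"collinear {pair_name} design on the observed-gene subset of "
                f"sample column {j} (condition number {cond:.3g})"
            )
        coefs[j] = np.linalg.lstsq(sub, Z[obs, j], rcond=None)[0]
    return coefs


def infer_program_levels(
    Z: ExpressionMatrix,
    W: GeneWeightMap,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> pd.DataFrame:
    """Per-sample OLS fit of one program pair.

    Returns a DataFrame indexed by sample id with columns ``b`` (intercept),
    ``s_confounder`` and ``s_program``.
    """
    if Z.scale != "standardized":
        raise ValidationError("program inference expects a standardized matrix")
    Zs, Ws = align_genes(Z, W, min_overlap)
    design = np.column_stack(
        [np.ones(Zs.n_genes), Ws.confounder_weights, Ws.program_weights]
    )
    coefs = _ols_levels(Zs.values, design, min_overlap, W.pair_name)
    return pd.DataFrame(
        coefs, index=Zs.sample_ids, columns=["b", "s_confounder", "s_program"]
    )


class ProgramScorer(BaseEstimator, TransformerMixin):
    """Transformer mapping standardized expression profiles to R/SI levels.

    Follows the scikit-learn convention of samples as rows: ``X`` is a
    DataFrame of shape (n_samples, n_genes) with gene ids as columns.
    ``fit`` establishes the reference used to standardize levels — the
    healthy controls when given, otherwise the fitted cohort itself
    (``reference_mode_ = "cohort"``, the only self-contained option for
    cohorts without healthy subjects).  ``transform`` returns raw levels
    (s_R, s_T, s_SI, s_IM1), standardized levels (z_R, z_SI) and the balance
    score z_R - z_SI.

    Parameters
    ----------
    weights_rt, weights_si
        Predefined :class:`~risi.io.GeneWeightMap` for the R/T and SI/IM1
        pairs.
    min_overlap
        Minimum measured genes shared with each weight map.
    ddof
        Delta degrees of freedom of the reference SD (0 = population SD).
    """

    def __init__(
        self,
        weights_rt: GeneWeightMap | None = None,
        weights_si: GeneWeightMap | None = None,
        min_overlap: int = DEFAULT_MIN_OVERLAP,
        ddof: int = 0,
    ):
        self.weights_rt = weights_rt
        self.weights_si = weights_si
        self.min_overlap = min_overlap
        self.ddof = ddof

    def _raw_levels(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.weights_rt is None or self.weights_si is None:
            raise ValidationError("ProgramScorer needs both weight maps")
        Z = ExpressionMatrix(X.T.astype(float), "standardized")
        rt = infer_program_levels(Z, self.weights_rt, self.min_overlap)
        si = infer_program_levels(Z, self.weights_si, self.min_overlap)
        return pd.DataFrame(
            {
                "b_R_pair": rt["b"],
                "s_T": rt["s_confounder"],
                "s_R": rt["s_program"],
                "b_SI_pair": si["b"],
                "s_IM1": si["s_confounder"],
                "s_SI": si["s_program"],
            }
        )

    def fit(self, X: pd.DataFrame, y=None, controls: list[str] | None = None):
        """Learn the level-standardization reference from X (or its controls)."""
        levels = self._raw_levels(X)
        if controls is not None:
            missing = [c for c in controls if c not in levels.index]
            if missing:
                raise ValidationError(f"controls not in X: {missing[:5]}")
            ref = levels.loc[controls]
            if len(ref) < 3:
                raise ValidationError("need >= 3 controls with inferred levels")
            self.reference_mode_ = "controls"
        else:
            ref = levels
            self.reference_mode_ = "cohort"
        self.ref_mean_ = ref[["s_R", "s_SI"]].mean()
        self.ref_sd_ = ref[["s_R", "s_SI"]].std(ddof=self.ddof)
        if (self.ref_sd_ == 0).any():
            raise ValidationError("zero reference SD for program levels")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "ref_mean_")
        levels = self._raw_levels(X)
        levels["z_R"] = (levels["s_R"] - self.ref_mean_["s_R"]) / self.ref_sd_["s_R"]
        levels["z_SI"] = (levels["s_SI"] - self.ref_mean_["s_SI"]) / self.ref_sd_["s_SI"]
        levels["balance"] = levels["z_R"] - levels["z_SI"]
        levels["reference_mode"] = self.reference_mode_
        return levels


def score_cohort(
    Z: ExpressionMatrix,
    weights_rt: GeneWeightMap,
    weights_si: GeneWeightMap,
    control_ids: list[str] | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> pd.DataFrame:
    """Infer, standardize and balance-score program levels for a cohort.

    Functional wrapper over :class:`ProgramScorer` taking the genes x samples
    orientation used by the file formats.
    """
    scorer = ProgramScorer(weights_rt, weights_si, min_overlap=min_overlap)
    X = Z.data.T
    scorer.fit(X, controls=control_ids)
    return scorer.transform(X)


def standardize_levels(
    levels: pd.DataFrame, control_ids: list[str] | None, ddof: int = 0
) -> pd.DataFrame:
    """Standardize raw s_R/s_SI against controls and attach the balance score.

    Falls back to the cohort itself as reference when ``control_ids`` is
    None (flagged in ``reference_mode``).
    """
    out = levels.copy()
    if control_ids is not None:
        if len(control_ids) < 3:
            raise ValidationError("need >= 3 controls with inferred levels")
        ref = levels.loc[control_ids]
        mode = "controls"
    else:
        ref, mode = levels, "cohort"
    for prog in ("R", "SI"):
        mu = ref[f"s_{prog}"].mean()
        sd = ref[f"s_{prog}"].std(ddof=ddof)
        if sd == 0:
            raise ValidationError(f"zero control SD for s_{prog}")
        out[f"z_{prog}"] = (levels[f"s_{prog}"] - mu) / sd
    out["balance"] = out["z_R"] - out["z_SI"]
    out["reference_mode"] = mode
    return out


def balance_score(levels: pd.DataFrame) -> pd.Series:
    """R/SI-balance score: standardized R level minus standardized SI level."""
    return levels["z_R"] - levels["z_SI"]


# ---------------------------------------------------------------------------
# protein-based levels (cohorts measured by proteomics instead of RNA)


def fit_protein_weight_map(
    levels: pd.DataFrame, protein_table: pd.DataFrame, min_n: int = 10
) -> pd.DataFrame:
    """Per-protein Pearson correlations with z_R and z_SI (the 2D protein map).

    ``protein_table`` is samples x proteins; pairwise-complete samples are
    used per protein, and proteins observed in fewer than ``min_n`` samples
    (or constant) get missing weights with a warning.
    """
    shared = levels.index.intersection(protein_table.index)
    if len(shared) < min_n:
        raise ValidationError(
            f"only {len(shared)} samples with both levels and proteins"
        )
    prot = protein_table.loc[shared]
    out = pd.DataFrame(index=protein_table.columns, columns=["w_R", "w_SI"], dtype=float)
    skipped = []
    for p in prot.columns:
        obs = prot[p].notna()
        if obs.sum() < min_n or prot.loc[obs, p].std() == 0:
            skipped.append(p)
            continue
        x = prot.loc[obs, p]
        out.loc[p, "w_R"] = float(np.corrcoef(x, levels.loc[x.index, "z_R"])[0, 1])
        out.loc[p, "w_SI"] = float(np.corrcoef(x, levels.loc[x.index, "z_SI"])[0, 1])
    if skipped:
        warnings.warn(
            f"{len(skipped)} proteins without weights (too few samples or "
            f"constant), e.g. {skipped[0]!r}"
        )
    return out


def infer_levels_from_proteins(
    protein_table: pd.DataFrame,
    pmap: pd.DataFrame,
    min_overlap: int = 10,
    standardize_profiles: bool = True,
) -> pd.DataFrame:
    """Infer R and SI levels from protein profiles via the 2D weight map.

    Each sample's profile (standardized across proteins by default) is
    regressed on [intercept, w_R, w_SI] jointly — a single two-predictor
    model since the map is one 2D map.  Returns b, s_R, s_SI per sample.
    """
    weights = pmap.dropna()
    shared = protein_table.columns.intersection(weights.index)
    if len(shared) < min_overlap:
        raise ValidationError(
            f"only {len(shared)} proteins shared with the weight map (< {min_overlap})"
        )
    prof = protein_table[shared].astype(float)
    if standardize_profiles:
        mu = prof.mean(axis=1)
        sd = prof.std(axis=1, ddof=0)
        if (sd == 0).any():
            raise ValidationError("constant protein profile cannot be standardized")
        prof = prof.sub(mu, axis=0).div(sd, axis=0)
    design = np.column_stack(
        [np.ones(len(shared)), weights.loc[shared, "w_R"], weights.loc[shared, "w_SI"]]
    )
    coefs = _ols_levels(prof.T.to_numpy(), design, min_overlap, "protein_map")
    return pd.DataFrame(coefs, index=prof.index, columns=["b", "s_R", "s_SI"])


DEFAULT_R_MARKERS = ("CXCL11", "IFNg")
DEFAULT_SI_MARKERS = ("IL6", "IL8")


def biomarker_proxies(
    protein_table: pd.DataFrame,
    r_markers: tuple[str, ...] = DEFAULT_R_MARKERS,
    si_markers: tuple[str, ...] = DEFAULT_SI_MARKERS,
    zscore: bool = True,
) -> pd.DataFrame:
    """Few-protein proxies: R ~ mean(CXCL11, IFNg), SI ~ mean(IL6, IL8).

    Marker proteins are z-scored across the cohort before averaging (they sit
    on different dynamic ranges); ``zscore=False`` averages raw values.  A
    sample missing one marker of a pair degrades to the available marker and
    is flagged ``partial``.
    """
    missing = [m for m in (*r_markers, *si_markers) if m not in protein_table.columns]
    if missing:
        raise ValidationError(f"marker proteins absent from table: {missing}")
    cols = list(r_markers) + list(si_markers)
    prot = protein_table[cols].astype(float)
    if zscore:
        prot = (prot - prot.mean()) / prot.std(ddof=0)
    out = pd.DataFrame(index=protein_table.index)
    out["R_proxy"] = prot[list(r_markers)].mean(axis=1)
    out["SI_proxy"] = prot[list(si_markers)].mean(axis=1)
    out["balance_proxy"] = out["R_proxy"] - out["SI_proxy"]
    out["partial"] = prot.isna().any(axis=1)
    return out
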