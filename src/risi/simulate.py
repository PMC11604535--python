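"""Synthetic cohorts with the latent structure the R/SI analysis assumes.

The generator draws per-sample latent levels of four programs (R, T, SI,
IM1) from condition-specific multivariate normals, builds log-scale gene
expression as baseline + weights * latents + noise, and exponentiates to a
linear scale so the full preprocessing pipeline (zeros to missing, log2,
standardization) is exercised.  Condition means encode the study design:
moderate infection activates R at least as much as SI, sepsis activates SI
well above R, healthy sits at the origin.  Proteins load linearly on the
latents, per-cell latents scatter around patient means, and survival hazards
increase with SI and decrease with R.  Every generator is a pure function of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import (
    CohortBundle,
    ExpressionMatrix,
    GeneWeightMap,
    SampleTable,
    ValidationError,
)

LATENTS = ("R", "T", "SI", "IM1")

DEFAULT_LATENT_MEANS = {
    "healthy": (0.0, 0.0, 0.0, 0.0),
    "moderate_infection": (2.0, 0.5, 1.0, 0.3),
    "sepsis": (0.5, 0.5, 2.5, 0.5),
}


def default_latent_cov() -> np.ndarray:
    """Unit-SD latent covariance with a +0.5 R-SI correlation.

    R and SI are both activation arms of the immune response and co-vary
    across individuals within a condition; the positive correlation also
    concentrates the within-group spread of the balance score R - SI, which
    is what makes the balance a sharp discriminator between conditions.
    """
    cov = np.eye(4)
    cov[0, 2] = cov[2, 0] = 0.5  # corr(R, SI)
    return cov


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults are the assumed conditions of the analysis: 2000 genes, 100
    samples per condition, unit latent SD, gene-level noise SD 1.0 (on the
    log2 scale, same order as the latent signal), near-orthogonal weights
    (max pairwise |corr| 0.1), survival log-hazards +0.7 on SI and -0.7 on R
    with the baseline hazard tuned to a 59% event rate by day 28.
    """

    n_genes: int = 2000
    n_per_condition: dict = field(
        default_factory=lambda: {
            "healthy": 100,
            "moderate_infection": 100,
            "sepsis": 100,
        }
    )
    latent_means: dict = field(default_factory=lambda: dict(DEFAULT_LATENT_MEANS))
    latent_cov: np.ndarray = field(default_factory=lambda: default_latent_cov())
    weight_orthogonality: float = 0.1
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    missing_rate: float = 0.0
    cells_per_patient: int = 200
    cell_sd: float = 0.5
    beta_si: float = 0.7
    beta_r: float = -0.7
    target_event_rate: float = 0.59
    horizon_days: float = 28.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("GeneratorConfig requires an explicit seed")
        self.latent_cov = np.asarray(self.latent_cov, dtype=float)
        eig = np.linalg.eigvalsh(self.latent_cov)
        if eig.min() < -1e-10:
            raise ValidationError("latent covariance not positive semi-definite")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0, 1)")


@dataclass
class GroundTruth:
    """True latents/weights/loadings kept alongside every generated artifact."""

    latents: pd.DataFrame | None = None  # samples x (R, T, SI, IM1)
    weights: pd.DataFrame | None = None  # genes x (R, T, SI, IM1)
    protein_loadings: pd.DataFrame | None = None  # proteins x latents
    cell_latents: pd.DataFrame | None = None  # cells x latents


def generate_weights(
    n_genes: int, orthogonality: float = 0.1, seed: int | None = None
) -> tuple[GeneWeightMap, GeneWeightMap, GroundTruth]:
    """Draw four near-orthogonal standard-normal weight vectors.

    If the raw draws already satisfy the pairwise |correlation| target they
    are returned as-is; otherwise the centered vectors are orthogonalized
    (QR) and rescaled to unit variance, which makes correlations exactly 0.
    """
    if orthogonality <= 0:
        raise ValidationError("orthogonality target must be > 0")
    if n_genes < 200:
        raise ValidationError("need n_genes >= 200 for stable synthetic weights")
    rng = np.random.default_rng(seed)
    V = rng.standard_normal((n_genes, 4))
    corr = np.corrcoef(V.T)
    if np.abs(corr - np.eye(4)).max() > orthogonality:
        Q, _ = np.linalg.qr(V - V.mean(axis=0))
        V = Q / Q.std(axis=0, ddof=0)
    genes = pd.Index([f"g{i:05d}" for i in range(n_genes)])
    truth = pd.DataFrame(V, index=genes, columns=list(LATENTS))
    w_rt = GeneWeightMap(
        pd.DataFrame({"confounder": truth["T"], "program": truth["R"]}), "R_T"
    )
    w_si = GeneWeightMap(
        pd.DataFrame({"confounder": truth["IM1"], "program": truth["SI"]}), "SI_IM1"
    )
    return w_rt, w_si, GroundTruth(weights=truth)


def _draw_latents(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows, ids, conds = [], [], []
    for cond, n in cfg.n_per_condition.items():
        mean = np.asarray(cfg.latent_means[cond], dtype=float)
        rows.append(rng.multivariate_normal(mean, cfg.latent_cov, size=n))
        ids += [f"{cond}_{i:03d}" for i in range(n)]
        conds += [cond] * n
    lat = pd.DataFrame(np.vstack(rows), index=pd.Index(ids), columns=list(LATENTS))
    lat.attrs["condition"] = conds
    return lat


DEFAULT_PROTEIN_LOADINGS = {
    # protein: (R, T, SI, IM1) loadings; named so biomarker proxies run out
    # of the box (CXCL11/IFNg are R-loaded, IL6/IL8 SI-loaded analogs)
    "CXCL11": (1.0, 0.0, 0.1, 0.0),
    "IFNg": (0.9, 0.1, 0.0, 0.0),
    "CXCL10": (0.8, 0.0, 0.2, 0.0),
    "IL6": (0.1, 0.0, 1.0, 0.0),
    "IL8": (0.0, 0.0, 0.9, 0.1),
    "IL18bp": (0.2, 0.0, 0.7, 0.0),
}


def generate_proteins(
    latents: pd.DataFrame,
    loadings: pd.DataFrame | None = None,
    noise_sd: float = 0.5,
    n_noise_proteins: int = 10,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Linear protein panel: protein = loadings * latents + noise (NPX-like).

    The default panel carries the named biomarker analogs plus pure-noise
    filler proteins.
    """
    rng = np.random.default_rng(seed)
    if loadings is None:
        load = {k: list(v) for k, v in DEFAULT_PROTEIN_LOADINGS.items()}
        for i in range(n_noise_proteins):
            load[f"P{i:02d}"] = [0.0, 0.0, 0.0, 0.0]
        loadings = pd.DataFrame.from_dict(load, orient="index", columns=list(LATENTS))
    if list(loadings.columns) != list(LATENTS):
        raise ValidationError(f"protein loadings need columns {LATENTS}")
    signal = latents.to_numpy() @ loadings.to_numpy().T
    noise = rng.normal(0.0, noise_sd, size=signal.shape)
    table = pd.DataFrame(
        signal + noise, index=latents.index, columns=loadings.index
    )
    return table, GroundTruth(protein_loadings=loadings)


def generate_survival(
    latents: pd.DataFrame,
    baseline_hazard: float | None = None,
    beta_si: float = 0.7,
    beta_r: float = -0.7,
    target_event_rate: float = 0.59,
    horizon_days: float = 28.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Exponential survival with hazard lam * exp(beta_SI*SI + beta_R*R).

    When ``baseline_hazard`` is None it is tuned so the expected event
    fraction by the administrative-censoring horizon matches
    ``target_event_rate`` (closed-form under exponential censoring).  Age and
    sex are simulated independently of the hazard.
    """
    rng = np.random.default_rng(seed)
    eta = beta_si * latents["SI"].to_numpy() + beta_r * latents["R"].to_numpy()
    if baseline_hazard is None:
        def event_gap(log_lam: float) -> float:
            lam = np.exp(log_lam)
            return float(np.mean(1.0 - np.exp(-lam * np.exp(eta) * horizon_days))) - target_event_rate

        baseline_hazard = float(np.exp(brentq(event_gap, -20.0, 10.0)))
    if baseline_hazard <= 0:
        raise ValidationError("baseline hazard must be > 0")
    raw = rng.exponential(1.0 / (baseline_hazard * np.exp(eta)))
    event = raw <= horizon_days
    out = pd.DataFrame(
        {
            "time_days": np.minimum(raw, horizon_days),
            "event": event.astype(int),
            "age": rng.normal(65.0, 12.0, size=len(latents)),
            "sex": rng.integers(0, 2, size=len(latents)),
        },
        index=latents.index,
    )
    out.attrs["baseline_hazard"] = baseline_hazard
    return out


def inject_missing(
    X: ExpressionMatrix,
    rate: float,
    mode: str = "uniform",
    seed: int | None = None,
    n_biased_genes: int = 3,
    biased_rate: float = 0.9,
) -> ExpressionMatrix:
    """Mark cells missing at the requested rate.

    ``gene_biased`` concentrates missingness in ``n_biased_genes`` genes at
    ``biased_rate`` (to trigger the high-missingness gene-drop rule) on top
    of uniform background missingness.
    """
    if not 0 <= rate < 1:
        raise ValidationError("rate must be in [0, 1)")
    if rate == 0 and mode == "uniform":
        return X.copy()
    rng = np.random.default_rng(seed)
    vals = X.data.to_numpy(copy=True)
    if mode == "uniform":
        vals[rng.random(vals.shape) < rate] = np.nan
    elif mode == "gene_biased":
        if rate > 0:
            vals[rng.random(vals.shape) < rate] = np.nan
        biased = rng.choice(X.n_genes, size=n_biased_genes, replace=False)
        for g in biased:
            hit = rng.random(X.n_samples) < biased_rate
            vals[g, hit] = np.nan
    else:
        raise ValidationError(f"unknown missingness mode {mode!r}")
    out = ExpressionMatrix(
        pd.DataFrame(vals, index=X.gene_ids, columns=X.sample_ids), X.scale
    )
    return out


def _expression_from_latents(
    latents: np.ndarray,
    weights: np.ndarray,
    baseline: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Log2-scale genes x samples matrix: b_g + V * latent + noise."""
    signal = weights @ latents.T  # genes x samples
    noise = rng.normal(0.0, noise_sd, size=signal.shape)
    return baseline[:, None] + signal + noise


def generate_cohort(
    cfg: GeneratorConfig,
) -> tuple[CohortBundle, GroundTruth, GeneWeightMap, GeneWeightMap]:
    """Full bulk cohort: linear-scale expression, metadata, proteins, survival.

    Expression is built on the log2 scale and exponentiated so downstream
    preprocessing re-derives the log values; survival covers the sepsis
    samples (the high-mortality stratum).
    """
    rng = np.random.default_rng(cfg.seed)
    w_rt, w_si, truth_w = generate_weights(
        cfg.n_genes, cfg.weight_orthogonality, seed=rng.integers(2**31)
    )
    latents = _draw_latents(cfg, rng)
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    log_expr = _expression_from_latents(
        latents.to_numpy(), truth_w.weights.to_numpy(), baseline, cfg.noise_sd, rng
    )
    X = ExpressionMatrix(
        pd.DataFrame(
            np.exp2(log_expr), index=truth_w.weights.index, columns=latents.index
        ),
        "linear",
    )
    if cfg.missing_rate > 0:
        X = inject_missing(X, cfg.missing_rate, seed=int(rng.integers(2**31)))
    samples = SampleTable(
        pd.DataFrame(
            {"condition": latents.attrs["condition"], "dataset_id": "synthetic"},
            index=latents.index,
        )
    )
    proteins, truth_p = generate_proteins(latents, seed=int(rng.integers(2**31)))
    sepsis_ids = samples.ids_where("sepsis")
    survival = None
    if sepsis_ids:
        survival = generate_survival(
            latents.loc[sepsis_ids],
            beta_si=cfg.beta_si,
            beta_r=cfg.beta_r,
            target_event_rate=cfg.target_event_rate,
            horizon_days=cfg.horizon_days,
            seed=int(rng.integers(2**31)),
        )
    bundle = CohortBundle(X, samples, proteins=proteins, survival=survival)
    truth = GroundTruth(
        latents=latents,
        weights=truth_w.weights,
        protein_loadings=truth_p.protein_loadings,
    )
    return bundle, truth, w_rt, w_si


def generate_single_cell(
    cfg: GeneratorConfig,
    n_patients_per_group: dict | None = None,
    subpopulations: tuple[str, ...] = ("MS1", "MS2"),
    mean_depth: float = 2000.0,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth, GeneWeightMap, GeneWeightMap]:
    """Single-cell counts: per-cell latents scatter around patient means.

    Patients draw a latent mean from their condition's distribution; cells
    add N(0, cell_sd) scatter; counts arise by Poisson sampling with
    library-size scaling of the exponentiated per-cell log-expression.
    Returns the counts matrix (genes x cells), a cell annotation table
    (cell_id, patient_id, group, subpopulation), ground truth and the weight
    maps used.
    """
    if cfg.cells_per_patient < 20:
        raise ValidationError("cells_per_patient must be >= 20")
    groups = n_patients_per_group or {
        "control": 10,
        "moderate_infection": 10,
        "sepsis": 10,
    }
    rng = np.random.default_rng(cfg.seed)
    w_rt, w_si, truth_w = generate_weights(
        cfg.n_genes, cfg.weight_orthogonality, seed=int(rng.integers(2**31))
    )
    cond_of = {"control": "healthy"}
    cell_rows, ann_rows = [], []
    for group, n_pat in groups.items():
        mean = np.asarray(cfg.latent_means[cond_of.get(group, group)], dtype=float)
        for p in range(n_pat):
            pid = f"{group}_{p:02d}"
            pat_mean = rng.multivariate_normal(mean, cfg.latent_cov * 0.25)
            cell_lat = pat_mean + rng.normal(
                0.0, cfg.cell_sd, size=(cfg.cells_per_patient, 4)
            )
            subs = np.asarray(subpopulations)[
                np.arange(cfg.cells_per_patient) % len(subpopulations)
            ]
            for c in range(cfg.cells_per_patient):
                ann_rows.append(
                    {
                        "cell_id": f"{pid}_c{c:04d}",
                        "patient_id": pid,
                        "group": group,
                        "subpopulation": subs[c],
                    }
                )
            cell_rows.append(cell_lat)
    cell_latents = np.vstack(cell_rows)
    annotation = pd.DataFrame(ann_rows).set_index("cell_id")
    baseline = rng.normal(2.0, 0.5, size=cfg.n_genes)
    log_expr = _expression_from_latents(
        cell_latents,
        truth_w.weights.to_numpy(),
        baseline,
        cfg.noise_sd,
        rng,
    )
    rates = np.exp2(log_expr)
    rates = rates / rates.sum(axis=0, keepdims=True)
    depths = rng.poisson(mean_depth, size=rates.shape[1])
    counts = rng.poisson(rates * depths[None, :])
    X = ExpressionMatrix(
        pd.DataFrame(
            counts.astype(float), index=truth_w.weights.index, columns=annotation.index
        ),
        "linear",
    )
    truth = GroundTruth(
        weights=truth_w.weights,
        cell_latents=pd.DataFrame(
            cell_latents, index=annotation.index, columns=list(LATENTS)
        ),
    )
    return X, annotation, truth, w_rt, w_si
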