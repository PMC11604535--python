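"""R/SI-based endotype assignment and prognostic survival analysis.

Patients split into three endotypes: balance at or above a threshold is
"moderate imbalance"; low-balance patients subdivide into "high SI"
(standardized SI level in the cohort's upper tail) and "severe imbalance".
Endotype prognosis is evaluated with Kaplan-Meier curves, log-rank (or
Breslow/generalized-Wilcoxon) tests, and Cox proportional-hazards models
with age and sex as additional covariates (Efron tie handling).

The endotype thresholds are deliberately explicit inputs: the balance
threshold defaults to 0 on the standardized scale ("limited reduction" =
non-negative balance) and the high-SI cut to the cohort's top 15% of z_SI;
:func:`calibrate_thresholds` matches target endotype proportions instead.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, pairwise_logrank_test

from .io import ValidationError

ENDOTYPES = ("moderate_imbalance", "severe_imbalance", "high_SI")


def assign_endotypes(
    levels: pd.DataFrame,
    balance_thresh: float = 0.0,
    si_quantile: float = 0.85,
    si_thresh: float | None = None,
) -> pd.DataFrame:
    """Assign each patient to exactly one R/SI endotype.

    balance >= balance_thresh -> moderate_imbalance; otherwise high_SI if
    z_SI reaches the cohort ``si_quantile`` (or an absolute ``si_thresh``),
    else severe_imbalance.  Patients with missing levels are left
    unassigned (NaN) and listed in ``attrs["unassigned"]``.
    """
    need = levels[["balance", "z_SI"]]
    ok = need.notna().all(axis=1)
    if si_thresh is None:
        si_thresh = float(need.loc[ok, "z_SI"].quantile(si_quantile))
    endo = pd.Series(index=levels.index, dtype=object)
    bal, zsi = levels["balance"], levels["z_SI"]
    endo[ok & (bal >= balance_thresh)] = "moderate_imbalance"
    endo[ok & (bal < balance_thresh) & (zsi >= si_thresh)] = "high_SI"
    endo[ok & (bal < balance_thresh) & (zsi < si_thresh)] = "severe_imbalance"
    out = pd.DataFrame(
        {"endotype": endo, "balance": bal, "z_SI": zsi}
    )
    out.attrs["thresholds_used"] = {
        "balance_thresh": balance_thresh,
        "si_thresh": si_thresh,
    }
    out.attrs["unassigned"] = list(levels.index[~ok])
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} patients unassigned (missing levels)")
    return out


def calibrate_thresholds(
    levels: pd.DataFrame, target_proportions: dict[str, float]
) -> dict[str, float]:
    """Thresholds whose endotype shares match target cohort proportions.

    The balance threshold is the (1 - p_moderate) balance quantile; the SI
    threshold is the z_SI quantile, among low-balance patients, that leaves
    a p_high_SI share of the whole cohort above it.
    """
    p_mod = target_proportions["moderate_imbalance"]
    p_hi = target_proportions["high_SI"]
    bal = levels["balance"].dropna()
    balance_thresh = float(bal.quantile(1.0 - p_mod))
    low = levels.loc[levels["balance"] < balance_thresh, "z_SI"].dropna()
    frac_low = len(low) / len(bal)
    q = 1.0 - p_hi / frac_low
    si_thresh = float(low.quantile(np.clip(q, 0.0, 1.0)))
    return {"balance_thresh": balance_thresh, "si_thresh": si_thresh}


def km_logrank(
    assignments: pd.DataFrame,
    survival: pd.DataFrame,
    test: str = "logrank",
    min_group: int = 5,
) -> dict:
    """Kaplan-Meier curves per endotype plus overall and pairwise tests.

    ``survival`` is indexed by sample id with columns time_days and event.
    ``test`` selects log-rank or Breslow (generalized Wilcoxon) weighting.
    Groups below ``min_group`` patients are excluded with a warning.
    Returns a dict with ``curves`` (group -> KM survival table), ``overall_p``
    and ``pairwise_p``.
    """
    if test not in ("logrank", "breslow"):
        raise ValidationError(f"unknown test {test!r}")
    shared = assignments.dropna(subset=["endotype"]).index.intersection(survival.index)
    df = assignments.loc[shared, ["endotype"]].join(
        survival.loc[shared, ["time_days", "event"]]
    )
    sizes = df["endotype"].value_counts()
    small = sizes.index[sizes < min_group]
    if len(small):
        warnings.warn(f"excluding small groups {list(small)} (< {min_group})")
        df = df[~df["endotype"].isin(small)]
    if df["endotype"].nunique() < 2:
        raise ValidationError("need >= 2 endotype groups with enough patients")
    weightings = None if test == "logrank" else "wilcoxon"
    curves = {}
    for g, grp in df.groupby("endotype"):
        km = KaplanMeierFitter(label=str(g))
        km.fit(grp["time_days"], grp["event"])
        tab = km.survival_function_.join(km.confidence_interval_)
        tab["at_risk"] = [
            km.event_table.loc[: t, "at_risk"].iloc[-1] for t in tab.index
        ]
        curves[g] = tab
    overall = multivariate_logrank_test(
        df["time_days"], df["endotype"], df["event"], weightings=weightings
    )
    pairwise = pairwise_logrank_test(
        df["time_days"], df["endotype"], df["event"], weightings=weightings
    )
    return {
        "curves": curves,
        "overall_p": float(overall.p_value),
        "overall_statistic": float(overall.test_statistic),
        "pairwise_p": pairwise.summary["p"],
        "n_per_group": sizes.to_dict(),
    }


def cox_ph(
    survival: pd.DataFrame,
    covariates: pd.DataFrame,
    min_events: int = 30,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties, Wald CIs).

    ``covariates`` may hold the balance score as a continuous predictor or
    endotype indicators, plus age and a binary sex indicator.  Returns the
    per-covariate table of log-HR, CI bounds and p.
    """
    shared = survival.index.intersection(covariates.index)
    df = survival.loc[shared, ["time_days", "event"]].join(covariates.loc[shared])
    df = df.dropna()
    n_events = int(df["event"].sum())
    if n_events < min_events:
        raise ValidationError(
            f"only {n_events} events (< {min_events}); continuous-covariate Cox "
            "models need more events"
        )
    cph = CoxPHFitter(alpha=alpha)
    try:
        cph.fit(df, duration_col="time_days", event_col="event")
    except Exception as exc:  # lifelines raises several convergence errors
        raise ValidationError(f"Cox fit failed: {exc}") from exc
    summ = cph.summary
    pct = f"{100 * (1 - alpha):g}%"
    return pd.DataFrame(
        {
            "log_HR": summ["coef"],
            "HR": summ["exp(coef)"],
            "ci_lower": summ[f"coef lower {pct}"],
            "ci_upper": summ[f"coef upper {pct}"],
            "p": summ["p"],
        }
    )
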