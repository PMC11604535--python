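"""End-to-end orchestration: preprocess -> score -> validate -> associate ->
stratify -> survival, with a machine-readable manifest.

A run is configured by a single mapping (usually loaded from YAML) with one
mandatory root ``seed``; all stage randomness derives from it through named
substreams.  Inputs come either from files (``inputs:`` with expression /
metadata / weight-table paths) or from the synthetic generator
(``synthetic:`` with :class:`~risi.simulate.GeneratorConfig` fields).
Outputs are plain TSV/JSON; the manifest records the seed, package version,
and a sha256 per output, so identical configs produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    CohortBundle,
    ExpressionMatrix,
    ValidationError,
    read_expression,
    read_gene_weights,
    read_sample_table,
    write_expression,
)
from .preprocess import PreprocessConfig, preprocess_pipeline
from .scoring import score_cohort
from .simulate import GeneratorConfig, generate_cohort
from .survival import assign_endotypes, cox_ph, km_logrank
from .validation import (
    heldout_variance,
    percent_significant,
    permuted_null_heldout,
    tpr_fpr_f1,
)

_STAGE_OFFSETS = {"generate": 1, "validate": 2, "associate": 3, "survival": 4}


def _substream(seed: int, stage: str) -> int:
    return (int(seed) * 1000 + _STAGE_OFFSETS[stage]) % (2**31)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(inputs: dict):
    X = read_expression(inputs["expression"], scale_hint=inputs.get("scale", "linear"))
    samples = read_sample_table(inputs["meta"])
    w_rt = read_gene_weights(inputs["weights_rt"], "R_T")
    w_si = read_gene_weights(inputs["weights_si"], "SI_IM1")
    proteins = (
        pd.read_csv(inputs["proteins"], sep="\t", index_col=0)
        if "proteins" in inputs
        else None
    )
    survival = (
        pd.read_csv(inputs["survival"], sep="\t", index_col=0)
        if "survival" in inputs
        else None
    )
    bundle = CohortBundle(X, samples, proteins=proteins, survival=survival)
    return bundle, w_rt, w_si


def run_bulk_analysis(cfg: dict, outdir: str | Path) -> dict:
    """Run the full bulk pipeline and return the manifest dict.

    Stage outputs land in ``outdir``: preprocessed matrix, levels table,
    validation JSON, endotype table, survival statistics, and
    ``manifest.json``.
    """
    if "seed" not in cfg or cfg["seed"] is None:
        raise ValidationError("run config must set a seed")
    seed = int(cfg["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    if "synthetic" in cfg:
        gen = GeneratorConfig(**{**cfg["synthetic"], "seed": _substream(seed, "generate")})
        bundle, truth, w_rt, w_si = generate_cohort(gen)
    elif "inputs" in cfg:
        bundle, w_rt, w_si = _load_inputs(cfg["inputs"])
    else:
        raise ValidationError("config needs either 'synthetic' or 'inputs'")

    # preprocess
    pp_cfg = PreprocessConfig(**cfg.get("preprocess", {}))
    controls = bundle.samples.control_ids
    Z, pp_report = preprocess_pipeline(bundle.expression, controls, pp_cfg)
    outputs["preprocessed"] = outdir / "preprocessed.tsv"
    write_expression(Z, outputs["preprocessed"])

    # score
    levels = score_cohort(Z, w_rt, w_si, control_ids=controls)
    levels = levels.join(bundle.samples.frame["condition"])
    outputs["levels"] = outdir / "levels.tsv"
    levels.to_csv(outputs["levels"], sep="\t", float_format="%.8g")

    # validate
    vcfg = cfg.get("validation", {})
    n_folds = int(vcfg.get("n_folds", 10))
    n_perm = int(vcfg.get("n_perm", 20))
    vseed = _substream(seed, "validate")
    held = heldout_variance(Z, w_rt, w_si, n_folds=n_folds, seed=vseed)
    null = permuted_null_heldout(
        Z, w_rt, w_si, n_folds=n_folds, n_perm=n_perm, seed=vseed
    )
    val = {
        "percent_significant": {
            m: percent_significant(held[f"r2_{m}"].to_numpy(), null[m])
            for m in ("joint", "R_only", "SI_only")
        },
        "tpr_fpr_curve": tpr_fpr_f1(
            held["r2_joint"].to_numpy(), null["joint"][: len(held)]
        ).to_dict(orient="records"),
        "n_folds": n_folds,
        "n_perm": n_perm,
    }
    outputs["validation"] = outdir / "validation.json"
    outputs["validation"].write_text(json.dumps(val, indent=2, sort_keys=True))

    # stratify + survival
    stats_out: dict = {"preprocess": pp_report, "validation_summary": val["percent_significant"]}
    ecfg = cfg.get("endotypes", {})
    sepsis = levels.loc[levels["condition"] == "sepsis"]
    if len(sepsis) >= 10:
        assign = assign_endotypes(
            sepsis,
            balance_thresh=float(ecfg.get("balance_thresh", 0.0)),
            si_quantile=float(ecfg.get("si_quantile", 0.85)),
        )
        outputs["endotypes"] = outdir / "endotypes.tsv"
        assign.to_csv(outputs["endotypes"], sep="\t", float_format="%.8g")
        stats_out["endotype_counts"] = (
            assign["endotype"].value_counts().to_dict()
        )
        if bundle.survival is not None:
            surv = bundle.survival
            try:
                km = km_logrank(assign, surv)
                stats_out["logrank_overall_p"] = km["overall_p"]
            except ValidationError as exc:
                stats_out["logrank_overall_p"] = f"skipped: {exc}"
            cov = sepsis[["balance"]].join(surv[["age", "sex"]], how="inner")
            try:
                cox = cox_ph(surv, cov, min_events=int(cfg.get("cox_min_events", 30)))
                stats_out["cox"] = {
                    k: {c: float(cox.loc[k, c]) for c in ("log_HR", "p")}
                    for k in cox.index
                }
            except ValidationError as exc:
                stats_out["cox"] = f"skipped: {exc}"
    outputs["summary"] = outdir / "summary.json"
    outputs["summary"].write_text(json.dumps(stats_out, indent=2, sort_keys=True, default=str))

    manifest = {
        "risi_version": __version__,
        "seed": seed,
        "config": cfg,
        "outputs": {k: {"path": p.name, "sha256": _sha256(p)} for k, p in outputs.items()},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    return manifest


def render_report(outdir: str | Path) -> list[Path]:
    """Render static figures from a completed run directory.

    Produces the R-vs-SI scatter colored by condition and the balance-score
    distributions; sections with missing inputs are skipped with a notice.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    figures = []
    levels_path = outdir / "levels.tsv"
    if not levels_path.exists():
        print("report: levels.tsv absent, nothing to render")
        return figures
    levels = pd.read_csv(levels_path, sep="\t", index_col=0)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for cond, grp in levels.groupby("condition"):
        axes[0].scatter(grp["z_SI"], grp["z_R"], s=8, alpha=0.6, label=cond)
        axes[1].hist(grp["balance"], bins=30, alpha=0.5, label=cond)
    axes[0].set_xlabel("SI level (z)")
    axes[0].set_ylabel("R level (z)")
    axes[0].axline((0, 0), slope=1, color="grey", lw=0.8)
    axes[0].legend(fontsize=7)
    axes[1].set_xlabel("R/SI-balance score")
    axes[1].set_ylabel("patients")
    fig.tight_layout()
    path = outdir / "report_levels.png"
    fig.savefig(path, dpi=120, metadata={"Software": None})
    plt.close(fig)
    figures.append(path)
    return figures
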