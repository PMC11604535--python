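# risi

Analysis of infection transcriptomes through the lens of two predefined
transcriptional programs: **resistance** (R), the immune program associated
with detection and elimination of pathogens, and **systemic inflammation**
(SI). Sepsis carries a reproducible molecular fingerprint of a *low R
relative to SI*; `risi` quantifies that fingerprint per sample (or per
single cell), validates it, and uses it for prognosis-relevant patient
stratification. The intended users are computational immunologists working
with bulk or single-cell blood transcriptomes of infection cohorts.

## The model

Each sample's preprocessed expression profile $Z_i$ (a vector over genes)
is modeled as a weighted sum of a program of interest and its confounder,
using externally derived per-gene weight vectors $V$:

$$Z_i = b_i + s_{T,i}\,V_T + s_{R,i}\,V_R \qquad\qquad
  Z_i = b_i + s_{IM1,i}\,V_{IM1} + s_{SI,i}\,V_{SI}$$

Both pairs are fitted by ordinary least squares, separately, per sample.
The program coefficients $s_{R,i}$ and $s_{SI,i}$ are the sample's R and SI
*levels*. After standardizing each level against the healthy controls, the
**R/SI-balance score** is

$$\mathrm{balance}_i = z_{R,i} - z_{SI,i}$$

with negative values ("impaired balance") typifying sepsis and non-negative
values typifying moderate infection. Downstream, the package provides:

- the four-step preprocessing pipeline (missing-data policy with KNN
  imputation, log2, per-sample and control-anchored per-gene
  standardization) — `risi.preprocess`;
- program-level inference and balance scoring, including protein-based
  levels and few-protein biomarker proxies — `risi.scoring`
  (sklearn-compatible `ProgramScorer`);
- hold-out explained-variance validation with permutation nulls, TPR/FPR/F1
  summaries, and per-sample inter-gene validation — `risi.validation`;
- benchmarking of candidate programs by disease response and cross-dataset
  covariation retrieval (covariation-F1) — `risi.benchmark`;
- per-cell scoring and patient-level signed log10 t-test response scores
  for annotated single-cell data — `risi.singlecell`;
- phenotype/protein variance-explained, 2D correlation maps, balance-marker
  ranking and hypergeometric enrichment — `risi.association`;
- R/SI endotype assignment (moderate imbalance / severe imbalance / high
  SI) with Kaplan-Meier, log-rank/Breslow and Cox analyses —
  `risi.survival`;
- a synthetic-cohort generator with full ground truth — `risi.simulate` —
  so every stage is testable without any data download.

## Worked example

```python
import numpy as np
from risi import GeneratorConfig, generate_cohort, preprocess_pipeline, score_cohort

cfg = GeneratorConfig(
    n_genes=1000,
    n_per_condition={"healthy": 60, "moderate_infection": 60, "sepsis": 60},
    seed=7,
)
bundle, truth, w_rt, w_si = generate_cohort(cfg)
Z, report = preprocess_pipeline(bundle.expression, bundle.samples.control_ids)
levels = score_cohort(Z, w_rt, w_si, control_ids=bundle.samples.control_ids)

condition = bundle.samples.frame["condition"]
print(levels.groupby(condition)[["z_R", "z_SI", "balance"]].mean().round(2))
r = np.corrcoef(levels["s_R"], truth.latents["R"])[0, 1]
print(f"recovery of the true R latent: r = {r:.3f}")
```

prints

```
                     z_R  z_SI  balance
condition
healthy            -0.00 -0.00    -0.00
moderate_infection  1.86  0.43     1.43
sepsis              0.24  1.94    -1.70
recovery of the true R latent: r = 0.932
```

Healthy controls sit at zero by construction (they are the standardization
reference). Moderate infection activates R more than SI (positive balance);
sepsis activates SI far above R (negative balance, the impaired-balance
fingerprint). The inferred per-sample R level correlates r = 0.93 with the
generator's true latent.

The same stages are available from the shell:

```bash
risi simulate --seed 7 --outdir fixtures/
risi preprocess --in fixtures/expression.tsv --meta fixtures/samples.tsv --out pre.tsv
risi score --expr pre.tsv --weights-rt fixtures/weights_rt.tsv \
    --weights-si fixtures/weights_si.tsv --meta fixtures/samples.tsv --out levels.tsv
risi run --config run.yaml        # full pipeline with manifest
```

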