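# lncsurv

Sparse multiple-linear-regression selection of survival-associated lncRNA
transcripts — an implementation of the **MlrLDAcp** procedure for joint
cancer-survival prediction and lncRNA–disease association scoring.

## The problem

Long noncoding RNAs (lncRNAs) are increasingly implicated in cancer, but
for most transcripts the link to a specific disease is unknown, and negative
examples are essentially unobtainable. MlrLDAcp sidesteps association
databases by going through clinical prognosis instead: transcripts whose
expression linearly predicts a patient's survival time are taken to be the
ones most closely associated with the disease. The package is aimed at
computational biologists working with paired tumor/normal expression
profiles plus a TCGA-style clinical table.

The model is

> *La* = *Led*<sup>sub</sup> · Θ + ε,

where *La* is the per-patient survival response (days to death for deceased
patients, days to last follow-up for alive ones — follow-up time is used
directly, with no censoring model), *Led*<sup>sub</sup> is a selected subset
of Δ candidate transcript columns from the samples × transcripts training
matrix *Led*, and Θ are the ordinary-least-squares coefficients
(survival-days per expression unit).

Candidates enter *Led* by a differential-expression screen (Welch *t*,
retain *P* < 0.001, order by ascending *P*). The subset is found by a
deterministic metaheuristic over the binary inclusion vector *X*:

1. **Seed** — set the bits of all candidates with *P* < 10⁻¹²; their count
   becomes the retention cap θ.
2. **Γ operation** (iteration *d* of *D* = 10) — flip all bits in a window
   centred at *Center* = C/2 + (C/D)·(−1)^(d−1)·⌊d/2⌋ with half-width
   ξ(d)·C/2, where the decay coefficient ξ falls from ≈ 0.93 to a floor of
   0.1 via tanh(2(D−d)/(D+1));
3. **stagnation kick** — if the leading θ bits repeat the previous
   iteration's, flip them;
4. **Γ correction** — keep only the θ one-bits of smallest index
   (most significant *P*);
5. **Stepwise** — bidirectional add/remove reduction of the active set,
   scored by Gaussian AIC, best move first, until neither direction
   improves; the best reduced set across all iterations is kept on a
   bulletin board and becomes *Led*<sup>sub</sup>.

The fitted |Θ_j|, standardized by each transcript's expression spread,
doubles as the transcript's disease-association score; evaluation helpers
provide fixed-horizon survival ROC/AUC and the leave-one-out
cross-validation protocol over known association pairs.

## Worked example

```python
from lncsurv import CohortSpec, MlrLDAcp, generate_cohort, survival_roc

cohort = generate_cohort(CohortSpec(
    n_transcripts=300, n_differential=40, n_causal=10,
    effect_size=5.0, noise_sd=10.0, seed=1,
))
model = MlrLDAcp.from_cohort(cohort.normal, cohort.tumor, cohort.clinical)
res = model.fit()
print(res.summary())
curve = survival_roc(res, model.exog, cohort.clinical)
print(f"5-year survival AUC: {curve.auc:.3f}")
```

prints

```
Survival-time multiple linear regression (Gamma-operation selection)
====================================================================
Samples: 176   Candidates: 41   Selected: 13
Residual standard error: 10.21 on 162 degrees of freedom
Overall model P value: 3.182e-282
AIC (selected model): 1332.71   best search AIC: 1332.71
--------------------------------------------------------------------
term                           theta       std err
Intercept                       2485         14.43
LNC00141                      -133.7        0.5111
...
5-year survival AUC: 1.000
```

The cohort planted 10 causal transcripts; the search recovers all 10 (three
extra weak transcripts survive the stepwise reduction at this seed), the
residual standard error ≈ 10 days matches the planted survival noise, and
the near-perfect predictions give a 5-year ROC AUC ≈ 1.0. The same pipeline
is available from the shell:

```bash
lncsurv run-all --seed 1 --outdir results/demo
```

which writes the cohort TSVs, the candidate ranking, the coefficient table,
diagnostics, the per-iteration search trace, and the survival ROC.

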