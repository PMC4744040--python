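# mr-lipids

Mendelian-randomization (MR) analysis of alcohol consumption and blood
lipids, built as a tested, reusable pipeline with a synthetic cohort
generator standing in for the access-controlled epidemiological data it
emulates.

## The scientific problem

Observational associations between low-to-moderate drinking and a
favourable lipid profile are confounded by demographic, behavioural and
health-related factors, and biased by reverse causation (sick people
abstain). MR sidesteps this by instrumenting alcohol consumption with
variants in alcohol-metabolism genes (*ADH1B*, *ADH1C*, *ADH4*): alleles
are randomized at conception, so an allele score that raises consumption
but is unrelated to confounders identifies the causal effect of drinking
on triglycerides (TG), total cholesterol, HDL-c and its subfractions
(HDL2-c, HDL3-c), LDL-c, small dense LDL-c, apoB, and Lp(a).

The estimator is two-stage least squares (2SLS) with a nonlinear second
stage. With exposure *x* = ln(alcohol g/wk + 1), unweighted score
*S* = Σⱼ Gⱼ (count of consumption-raising alleles), and covariates
*W* = (sex, age, PC1, PC2):

1. **first stage** — x = α₀ + α₁S + α'W + ε, with the weak-instrument
   diagnostics: partial R² of the score and the nested-model F
   (rule of thumb: F > 10);
2. **quartiling** — the fitted x̂ is cut at its empirical quartiles;
3. **second stage** — lipid = β₂1{q2} + β₃1{q3} + β₄1{q4} + γ'W + e,
   quartile 1 the reference, with per-quartile Wald tests and a 3-df
   overall Wald test. Skewed lipids are analysed on the ln scale and
   reported as percent changes 100·(e^β − 1).

A continuous-exposure 2SLS (with the proper residual correction, its
point estimate verified against the closed-form IV solution) handles
linear effects and oracle checks.

The package also implements the surrounding study machinery: phenotype
derivation (beverage counts → grams of ethanol, Friedewald LDL-c,
HDL2-c = HDL-c − HDL3-c, Lp(a) × 1.326, drinker categories), the
three-step instrument screen (LD with lipid loci r² > 0.2, confounder
correlation |r| > 0.1, pairwise LD r² > 0.7 with deterministic
functional-impact tie-breaking), observational category regressions,
and sensitivity reruns excluding heavy / never / former drinkers.

## Worked example

```python
from mrlipids import pipeline
from mrlipids.simulate import SimulationConfig, generate_cohort

cohort, truth = generate_cohort(SimulationConfig(seed=1))      # n = 10,893
derived = pipeline.prepare_cohort(cohort)
scored, report, score, survivors = pipeline.select_instruments(derived)
results = pipeline.run_mr(scored, pipeline.AnalysisPlan(outcomes=("tg",)))
print(pipeline.make_report(results))
```

prints (abridged):

```
tg: n=10308, first-stage F=7.58, partial R2=0.07%, overall Wald p=0.149  [weak instrument: F <= 10]
  q2 vs q1: beta=-0.006 (-0.6%) [-0.040, +0.027], p=0.702
  q3 vs q1: beta=-0.062 (-6.0%) [-0.137, +0.012], p=0.102
  q4 vs q1: beta=-0.037 (-3.6%) [-0.124, +0.050], p=0.402
```

Read: on this draw the five-SNP score explains 0.07% of exposure
variance (F = 7.6, flagged weak), and the third predicted-consumption
quartile shows a 6.0% lower TG than the first — the largest quartile
contrast, as the peaked generating curve implies — though a single
weak-instrument draw of this size is not individually significant.
The replicate studies below characterise the estimator's behaviour
properly.

The same pipeline is available from the shell:

```bash
mr-lipids all --out results/run1 --seed 1
```

## Analysis scripts

`analysis/01…06` are thin narrative drivers over the library: simulate
the default cohort, derive phenotypes, screen instruments, run the
quartiled-IV and sensitivity analyses, and run the replicate studies
(calibration, linear-effect recovery vs confounded OLS, Wald-test size,
peaked-curve quartile pattern). Each writes its tables under
`results/`.

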