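# coroflow

Computation of absolute coronary blood flow and coronary microvascular
resistance (CMVR) from two-view angiographic reconstructions and invasive
pressures, with a synthetic-cohort generator and the subgroup statistics
used to compare CMVR between patient groups (e.g. men vs women).

## The problem

Coronary microvascular dysfunction is common — especially in women — but
hard to measure: intracoronary pressure is easy to record with a pressure
wire, while absolute flow (ml/min) is not. A computational route closes the
gap: reconstruct the artery of interest as a 3D axisymmetric rigid lumen
from two angiographic projections at least 30° apart, prescribe the
measured proximal (Pa) and distal (Pd) pressures at inlet and outlet,
solve steady laminar Newtonian flow (blood: μ = 0.0035 Pa·s,
ρ = 1056 kg/m³), and read off the absolute flow `Q`. The physiological
indices follow:

```
CMVR = 1000 · Pd / Q        (Wood units, mmHg·min/L; per state)
CFR  = Q_hyper / Q_base     (coronary flow reserve)
FFR  = Pd / Pa              (hyperaemic; fractional flow reserve)
```

`coroflow` implements this pipeline for synthetic cohorts with known ground
truth — patient-level angiograms and pressures from such studies are not
publicly deposited — so every stage, from reconstruction through flow to
the rank-based subgroup tests, is exercised and validated end to end. It is
aimed at researchers in computational coronary physiology who want a
transparent, testable reference implementation of the full chain.

## What is inside

| module | contents |
|---|---|
| `coroflow.geometry` | stenosed axisymmetric phantoms, orthographic two-view projection, two-view reconstruction (`r(s)` = mean silhouette half-width) |
| `coroflow.flow_solver` | reduced-order pressure-drop model `ΔP = aQ + bQ²` (Poiseuille integral `a = ∫ 8μ/(πr⁴) ds`, Young–Tsai-type separation loss `b = K_e·ρ/2·(1/A_min − 1/A_out)²`, K_e = 1.52) |
| `coroflow.axisym` | steady axisymmetric Navier–Stokes oracle (stream-function/vorticity on a body-fitted grid) |
| `coroflow.physiology` | FFR / CMVR / CFR, consort-style exclusion accounting (inadequate gradient, reconstruction, meshing, convergence failures) |
| `coroflow.synthetic_cohort` | virtual patients: sex-specific lognormal CMVR, self-consistent pressures from the series stenosis + microvasculature circuit, covariates, failure injection |
| `coroflow.stats` | Shapiro–Wilk gate, Mann–Whitney U (tie + continuity corrected Z, exact permutation p for small n), Kruskal–Wallis, chi-square, Welch t / ANOVA, Cohen's d / Hedges' g, Pearson r, subgroup report |
| `coroflow.cli` | `coroflow simulate / reconstruct / solve / run / stats` |

## Worked example

```python
from coroflow import (GeneratorConfig, generate_cohort, apply_exclusions,
                      subgroup_report)

cfg = GeneratorConfig(n_male=109, n_female=35, seed=7)   # study-size cohort
cohort = generate_cohort(cfg)                            # two noisy views/case
results, consort, log = apply_exclusions(cohort.cases)   # reconstruct + solve

male = results[results.sex == "male"]["cmvr_hyper_wu"]
female = results[results.sex == "female"]["cmvr_hyper_wu"]
print("consort:", {k: v for k, v in consort.items() if v})
print(f"hyperaemic CMVR median: male {male.median():.0f} WU, "
      f"female {female.median():.0f} WU")
print(subgroup_report(results, ["sex"]).to_string(index=False))
```

prints

```
consort: {'inadequate_gradient': 16, 'included': 128}
hyperaemic CMVR median: male 684 WU, female 815 WU
variable             group_a_summary                   group_b_summary           test statistic        p  effect_size  significant
     sex male: 684 [503–867] (n=100) female: 815 [515–1.07e+03] (n=28) mann_whitney_u  Z = 1.29 0.195667    -0.394234        False
```

Reading this: 16 of 144 arteries were excluded because their hyperaemic
trans-lesional gradient was below 2 mmHg (flow is unidentifiable without an
epicardial gradient). The recovered medians sit near the generator's
configured sex-specific medians (680 / 860 WU); the Mann–Whitney Z of 1.29
(positive: the comparison group, women, tends to higher CMVR) does not
reach significance in this single replicate — a cohort of 35 women has
roughly 70–80% power at this effect size, so individual replicates are
expected to miss it at about this rate.

The same workflow is available from the shell:

```bash
coroflow simulate --out cohort/ --seed 7
coroflow run --cohort cohort/ --out run/
coroflow stats --results run/results.csv --out report/
```

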