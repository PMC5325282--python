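# eagle-demography

Demographic analysis of a resident, territorial golden eagle
(*Aquila chrysaetos*) population exposed to wind-turbine blade-strike
mortality, built for population ecologists and conservation analysts
who need to quantify what an annual mortality toll costs a
slow-reproducing raptor population.

The package implements the full analysis chain:

- **Known-fate survival** from radio-telemetry capture histories with
  staggered entry and censoring: product-binomial likelihood
  `L = Π S_i^(n_i−d_i)(1−S_i)^(d_i)` over seasonal (3-month) risk sets,
  a four-model candidate set {S(.), S(t), S(sex), S(sex×t)} ranked by
  AICc, annual survival `S = Π S_season` with delta-method SE and
  logit-scale confidence limits, and analytic "what-if" censoring of
  turbine or all human-related death causes.
- **Fecundity and sex ratio**: fledglings per occupied territory from
  nest surveys, G-tests of fledgling sex-ratio parity, and the female
  reproductive rate `f = rate × p_female` with a delta-method SE.
- **Potential growth rate** λ_p from a single-sex, post-breeding-pulse,
  5-stage matrix model, solved from the characteristic equation
  `λ⁴(λ − S_b) = S_b f S_j S_s³`, with delta-method SE and
  sensitivities by implicit differentiation.
- **Floater-to-breeder ratio** at Moffat's equilibrium:
  `F:B = (R − V)/(1 − S_f)` with recruitment `R = S_b f S_j S_s³` and
  vacancies `V = 1 − S_b`, cross-validated by simulation.
- **Demographic cost of mortality**: the replacement chain counting the
  breeding pairs whose entire output is consumed by one fatality of a
  given age, `P₀ = 1/(f2·φ(age))` compounded by the geometric
  per-round ratio `r = 2(1−S_b)/(f2·S_j S_s³ S_b)`, scaled to annual
  tolls and a resident-population footprint.
- **An individual-based population simulator** (monthly hazards,
  June breeding pulse, instant vacancy filling from a floater pool,
  radio-tagging with transmitter-life censoring) that generates all
  input tables and serves as the Monte-Carlo oracle for the analytic
  models.

See `docs/methods.md` for model details and assumptions.

## Worked example

Growth rate and equilibrium under turbine-censored vital rates
(S_j = 0.842, S_s = 0.921, S_f = 0.870, S_b = 0.920, f = 0.2313):

```python
>>> from eagle_demography import canonical_rates
>>> from eagle_demography import matrix_model as mm
>>> from eagle_demography import moffat_equilibrium as me
>>> from eagle_demography import demographic_cost as dc
>>> r = canonical_rates("turbine_censored")
>>> res = mm.lambda_se(mm.build_stage_model(r))
>>> round(res.lam, 3), round(res.SE, 3)
(1.04, 0.024)
>>> round(me.floater_breeder_ratio(r).fb_ratio, 2)
0.46
>>> ch = dc.replacement_chain(r, f2=0.638, fatality_age_months=40, k_rounds=6)
>>> [round(x, 3) for x in ch.series]
[2.256, 3.19, 3.578, 3.738, 3.805, 3.832, 3.844]
```

Read: without blade-strike mortality the population could grow ~4% per
year (λ_p = 1.040 ± 0.024) and would hold about one floater per two
breeding pairs' females (F:B ≈ 0.5) at equilibrium. One fatality at
the mean blade-strike age of 40 months consumes the annual output of
2.256 pairs, rising to 3.844 pairs once seven rounds of breeder
self-replacement are charged.

The same computations are available from the shell:

```
eagle-demog lambda --scenario turbine_censored
eagle-demog equilibrium --scenario human_censored
eagle-demog cost --annual-deaths 55
eagle-demog run-all --out results/report --seed 1
```

## Analysis scripts

The numbered drivers under `analysis/` run the full study end to end
and write their tables to `results/`:

```
python analysis/01_simulate_study.py        # synthetic telemetry study
python analysis/02_survival_estimates.py    # known-fate fits per scenario
python analysis/03_reproduction_sex_ratio.py
python analysis/04_potential_growth.py
python analysis/05_floater_equilibrium.py
python analysis/06_demographic_cost.py
```

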