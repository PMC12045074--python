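# tavicea

A cost-utility model comparing **transcatheter aortic valve implantation
(TAVI, SAPIEN 3)** with **surgical aortic valve replacement (SAVR)** in
patients with severe symptomatic aortic stenosis at low surgical risk, from
the perspective of the Swedish healthcare system (SEK, 2022 price level).
It is written for health economists and HTA analysts who want a fully
scripted, testable version of this class of model rather than a spreadsheet.

## The model

The analysis is a two-stage, cohort-level state-transition model:

1. **Acute phase (decision tree, first 30 days).** Each arm's expected
   procedure cost is the index cost plus rehabilitation and
   pacemaker-insertion components (unit cost × rate). Thirty-day adverse
   events either allocate the cohort to its day-30 health state — death,
   disabling stroke, or new atrial fibrillation (AF), treated as mutually
   exclusive branches with priority death > stroke > AF — or incur a one-off
   cost and return the patient to "alive and well" (MI, TIA, bleeding, AKI,
   non-disabling stroke).
2. **Markov model (monthly cycles, lifetime horizon).** Four states:
   *alive and well* → *treated AF* → *disabling stroke* → *dead*
   (absorbing), with no recovery transitions. "Alive and well" faces
   life-table background mortality *p*; AF and stroke occupants face
   1 − (1 − *p*)^HR with state-specific hazard ratios. Costs accrue by
   category (health states with a month-1 versus month-2+ split,
   rehospitalisation, reintervention, pacemaker complications, death), and
   QALYs accrue as occupancy × (age-matched population utility norm −
   state decrement) / 12. Costs and QALYs are discounted at 3 % per year,
   compounded per cycle.

Outputs follow the standard cost-utility summary: per-arm lifetime costs
*C* and QALYs *E*, the incremental cost-effectiveness ratio
ICER = ΔC/ΔE, net monetary benefit NMB = λ·ΔE − ΔC and net health benefit
NHB = ΔE − ΔC/λ at willingness-to-pay λ = 1,000,000 SEK/QALY. Uncertainty
is handled by one-at-a-time deterministic sensitivity analysis (tornado),
a probabilistic sensitivity analysis (1,000 Monte Carlo draws; CE plane
and acceptability curve), and a 16-scenario battery (horizons, discount
rates, structural toggles, alternative procedure costs).

The published cost inputs are bundled verbatim; the registry-derived event
probabilities, hazard ratios, utilities and the life table are **synthetic
stand-ins** (see `docs/methods.md`), so the bundled base case reproduces
the structure — not the headline numbers — of the original analysis. An
individual-level microsimulation of the identical model acts as an
independent correctness oracle for the cohort engine.

## Worked example

```python
import tavicea as tc

ps = tc.load_base_case()          # bundled fixture (printed costs + synthetic rest)
res = tc.run_base_case(ps)        # decision tree + Markov cohort, both arms
print(f"dCost {res.delta_cost:,.0f} SEK  dQALY {res.delta_qaly:.3f}  "
      f"ICER {res.icer:,.0f} SEK/QALY  NMB {res.nmb:,.0f} SEK")
```

prints

```
dCost 18,895 SEK  dQALY 0.329  ICER 57,374 SEK/QALY  NMB 310,432 SEK
```

i.e. on the synthetic base case TAVI gains 0.33 QALYs per patient for an
extra 18,895 SEK — about 57,000 SEK per QALY gained, far below the
1,000,000 SEK willingness-to-pay threshold, with a positive net monetary
benefit of ~310,000 SEK per patient. `res.to_frame()` gives the full
per-category cost breakdown at one year and over the lifetime.

The same analyses are available from the shell:

```bash
tavicea run  --out out/                 # base case: report + traces
tavicea psa  --seed 1 --out out/        # CE plane + CEAC (1,000 draws)
tavicea dsa  --out out/ --top 10        # tornado
tavicea scenario --all --out out/       # 16-scenario summary
tavicea synth --seed 7 --out inputs/    # generate synthetic inputs
tavicea oracle --arm tavi --n 100000 --seed 1 --out out/
```

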