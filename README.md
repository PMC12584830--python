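# ckdcea

A Markov cohort cost-effectiveness model for add-on therapy in chronic
kidney disease (CKD) with type 2 diabetes, built for health economists
and modellers evaluating finerenone and SGLT2 inhibitors on top of
standard of care (SoC, RAS-inhibitor based) from the Chinese
healthcare-system perspective.

The model tracks a cohort across CKD stages 1/2, 3, 4, 5 without
renal replacement therapy, and acute/post-acute dialysis and
transplant phases, crossed with a cardiovascular (CV) event-history
layer, in four-month cycles over a ten-year horizon.  All-cause death
is a competing per-cycle risk; first CV events move patients
irreversibly to post-CV compartments.  Strategy-specific transition
matrices and event risks are derived from the SoC inputs by applying
relative effects on the rate scale, `p' = 1 − (1 − p)^ratio`: the
relative eGFR decline rate scales stage 1–4 progression, the hazard
ratio (HR) for the composite kidney outcome scales late-stage renal
events, and HRs for first CV events and all-cause mortality scale the
corresponding risks.  Outcomes are discounted costs (CNY, 5%/year),
quality-adjusted life years (QALYs), and the net monetary benefit

    NMB = ΔQALY × WTP − ΔCost,    WTP = 268,074 CNY/QALY,

with one-way (tornado) and 1,000-iteration probabilistic sensitivity
analyses (beta/gamma/lognormal distributions fitted by method of
moments from each parameter's base case and range).

See `docs/methods.md` for the full model description and the
documented defaults used for the two inputs published only in
supplementary material (baseline CKD-stage distribution, CV event
mix).

## Worked example

```python
import ckdcea

ps = ckdcea.reference_parameter_set()      # packaged base-case inputs
arms, incs = ckdcea.run_cea(ps)            # triple vs SGLT2i, finerenone
print(ckdcea.results_table(arms, incs).to_string(index=False))
```

```
          comparison   strategy      cost  incr_cost  qalys  incr_qalys       nmb dominance
    triple vs SGLT2i     SGLT2i 226315.47       0.00  6.177       0.000      0.00
    triple vs SGLT2i     triple 170911.85  -55403.62  6.523       0.346 148243.96  dominant
triple vs finerenone finerenone 262443.02       0.00  5.953       0.000      0.00
triple vs finerenone     triple 170911.85  -91531.17  6.523       0.570 244232.29  dominant
```

Over ten years under the packaged inputs, triple therapy saves
55,404 CNY and gains 0.346 QALYs against SGLT2i therapy (NMB
148,244 CNY) and saves 91,531 CNY with 0.570 QALYs gained against
finerenone therapy — dominant (cheaper *and* more effective) in both
comparisons.  Absolute totals depend on the baseline severity mix
(see `docs/methods.md`); the dominance conclusion is stable across
every documented model setting.

The same analyses are available from the shell:

```sh
ckdcea run  --out-dir out            # traces + results table (CSV)
ckdcea run  --horizon 4 --out-dir out4   # short-horizon scenario
ckdcea owsa --comparator SGLT2i --out-dir owsa   # ranked tornado CSV
ckdcea psa  --n 1000 --seed 1 --out-dir psa      # CE plane + CEAC
ckdcea generate --seed 7 --out synthetic_params.yaml
```

Configs are YAML/JSON mirroring the parameter tables; a file with
`use_reference_inputs: true` starts from the packaged inputs and
overrides selected keys.

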