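# vssm — sequential-sampling models of value-based choice

`vssm` is a Python toolkit for simulating, fitting and comparing a family
of eight nested accumulator models of two-alternative value-based
decisions (e.g., choosing between two snack foods with rated desirability).
It is aimed at computational decision-making researchers who want to test
*which competitive architecture* — none, input-dependent, state-dependent,
or both, with or without attentional amplification — best explains
trial-level choices and reaction times.

## The models

Every alternative *x* gets one decision signal *d_x(t)*, accumulating in
10-ms steps until the first signal reaches a fixed threshold *D* = 100:

    d_x(t + Δt) = max{0, d_x(t) + f_x(t) + N(0, σ²)}

The value input is a step function, zero until a biologically constrained
predecision time T₀ = 150 ms and equal to the latent value V_x after.
The drift f_x distinguishes eight nested models (two alternatives; *y* the
other):

| id | df | drift f_x |
|----|----|-----------|
| RACE | 3 | b + g·v_x |
| NDD  | 3 | b + g·(v_x − v_y) |
| SNFI | 4 | b + g·(v_x − i_v·v_y) |
| DNFI | 4 | g·(b + v_x)/(s + v_x + v_y) |
| CA   | 4 | b + g·v_x − i_d·d_y |
| SCA  | 5 | b + g·(v_x − i_v·v_y) − i_d·d_y |
| DCA  | 5 | g·(b + v_x)/(s + v_x + v_y) − i_d·d_y |
| SSCA | 6 | SCA drift with v_x = V_x^a, a ≥ 1 |

The SSCA model — subtractive input competition, lateral inhibition between
accumulators, and a supralinear power law standing in for value-dependent
attention — is the headline: the exponent *a* > 1 overweights the
better option, producing a *positive* effect of the summed values on
choice accuracy that none of the seven simpler architectures can mimic.

Around the models the package provides:

* **Simulation** — vectorized first-passage simulation of trials, balanced
  experiment designs (10 value pairs, difference-bin balancing, side
  counterbalancing), and full synthetic studies (`vssm.simulate`,
  `vssm.design`).
* **Fitting** — the Monte-Carlo chi-square quantile objective (choice
  frequencies + 10/30/50/70/90% RT quantile bins per value pair, equal
  vector weights), Nelder–Mead with randomized restarts and common random
  numbers, null/saturated benchmarks, parity train/test splitting,
  likelihood-ratio tests, AICc and BIC (`vssm.fitting`).
* **Analysis** — the behavioral regression battery: trial classification,
  value normalization, complementary logistic (accuracy) and linear (RT)
  regressions in greater+lesser and |difference|+sum parameterizations,
  constant-normalized RT coefficients, absolute-value contrasts, category
  RT tests, and trial-weighted meta-aggregation (`vssm.analysis`).
* **Reference sets** — bundled fitted parameters for all eight models and
  frozen reference regression coefficients for regression-testing the
  whole pipeline (`vssm.reference`, `vssm.design.reproduce_model_rows`).

## A worked example

```python
from vssm import reproduce_model_rows

battery, comparison = reproduce_model_rows("SSCA", seed=0)
est, se = battery["accuracy_ds"].coef("sum")
print(f"accuracy sum effect: {est:+.3f} (SE {se:.3f})")
con, _ = battery["rt_correct_gl"].coef("const")
grt, _ = battery["rt_correct_gl"].coef("greater", normalized=True)
print(f"correct RT: constant {con:.3f} s, greater effect {grt:+.3f}")
```

prints

```
accuracy sum effect: +0.202 (SE 0.016)
correct RT: constant 1.103 s, greater effect -0.302
```

meaning: simulated at its fitted parameters, the SSCA model chooses the
better option *more* often as the total value of both options rises
(+0.202 log-odds per normalized value unit — the attentional overweighting
signature), its mean correct-choice RT baseline is ≈ 1.1 s, and a maximal
greater value speeds responses by ≈ 30% of that baseline. Running
`python examples/reproduce_reference_rows.py` prints the full battery next
to the frozen reference coefficients; `examples/simulate_and_analyze.py`
and `examples/fit_and_compare.py` walk through study simulation and model
comparison. The same operations are scriptable from a shell via the thin
`vssm` CLI (`simulate | fit | compare | analyze | recover | tables |
replay`), every run of which writes a manifest that replays byte-for-byte.

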