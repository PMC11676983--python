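# tmsdr — kinetics of reversible toehold-mediated strand displacement

DNA strand displacement circuits are designed around predictable reaction
kinetics, but the fluorophore/quencher labels used to *measure* those
kinetics can themselves shift the rate constants. This package is a tested
pipeline for quantifying that effect in reversible toehold-mediated strand
displacement (strand exchange) reactions:

* simulate the reversible mass-action model **X1 + X2 ⇌ X3 + X4** with
  lumped forward/backward rate constants kₐ, k_d (nM⁻¹ s⁻¹), including an
  exact closed-form progress curve used as an analytic oracle;
* convert fluorescence traces to substitution-ratio time courses by
  normalizing between a quenched-gate baseline and a fluorophore-only
  positive control;
* generate synthetic datasets with known ground truth (10 s sampling over
  90 min, triplicates, Gaussian noise) so every stage is testable;
* estimate (kₐ, k_d) by multi-start nonlinear least squares in log space,
  optionally clamping one rate, and report each estimate as a ratio to the
  theoretical rate for the toehold length (5.0×10⁻⁴ nM⁻¹ s⁻¹ at 6 nt).

The central steady-state quantity is the substitution ratio — the fraction
of invader strand displaced. At equal initial concentrations it depends
only on the rate-constant ratio:

    r_eq = √(kₐ/k_d) / (1 + √(kₐ/k_d))

so a construct whose labels inflate the backward rate shows a visibly
depressed plateau, not just a different time scale.

## Worked example

Generate a noisy synthetic dataset for a 5′-toehold construct with
asymmetric labelling and recover its rate constants:

```python
from tmsdr import (TMSDRSystem, SyntheticProtocol, CalibrationSet, generate,
                   normalize_to_substitution, aggregate_replicates, fit_rates,
                   build_report)
from tmsdr.conditions import DEFAULT_INITIAL
from tmsdr.estimation import render_report

system = TMSDRSystem(ka=1.74e-4, kd=8.51e-4,
                     toehold_orientation="five_prime",
                     modification="asymmetric", reporter_species="X3")
protocol = SyntheticProtocol(seed=7)   # 10 s sampling, 90 min, 3 replicates, 2% noise
dataset = generate(system, DEFAULT_INITIAL, protocol)

calib = CalibrationSet(dataset.baseline, dataset.positive_control,
                       reference_concentration=10.0)
courses = [normalize_to_substitution(t, calib) for t in dataset.reaction]
fit = fit_rates(aggregate_replicates(courses), DEFAULT_INITIAL)

print(f"ka = {fit.ka_hat:.3g} nM^-1 s^-1   (truth 1.74e-04)")
print(f"kd = {fit.kd_hat:.3g} nM^-1 s^-1   (truth 8.51e-04)")
print(render_report(build_report([(system, fit)])))
```

prints

```
ka = 0.00017 nM^-1 s^-1   (truth 1.74e-04)
kd = 0.000835 nM^-1 s^-1   (truth 8.51e-04)
toehold modification  ka_nM_s  ka_ratio  kd_nM_s  kd_ratio  equilibrium_substitution_pct      rss  converged
     5'   asymmetric  0.00017      0.34 0.000835       1.7                            31 0.065833       True
```

Both rates are recovered within a few percent from 2%-noise triplicates.
The ratio columns compare each estimate with the theoretical 6-nt-toehold
rate (kₐ-ratio 0.34: the forward reaction runs at about a third of theory;
k_d-ratio 1.7: the backward reaction is accelerated), and the last column
is the equilibrium substitution percentage the fitted rates predict at
equal 10 nM initials — ~31% for this construct.

The same pipeline is available from the shell (`tmsdr simulate`,
`tmsdr generate`, `tmsdr fit`, `tmsdr report`) driven by a YAML config; see
`tmsdr --help`.

## Reference conditions

`tmsdr.conditions.REFERENCE_CONDITIONS` holds the four labelled construct
variants (5′/3′ toehold × symmetric/asymmetric labelling) with their fitted
rate constants, which the test suite uses as operating points for
parameter-recovery studies and steady-state checks.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, by running the package end to end, the equilibrium substitution
percentage of each of the four reference constructs (long-time ODE
integration cross-checked against the equilibrium quadratic root, rounded
to the nearest 10%) and the eight fitted-rate-to-theory ratios at two
significant figures, writing them as JSON.

## Layout

```
src/tmsdr/
  reaction_model.py     mass-action ODE, closed-form oracle, equilibria
  observation_model.py  FRET prediction, normalization, replicate aggregation
  synthetic_data.py     protocol-faithful synthetic dataset generator
  estimation.py         multi-start least-squares rate estimation, reports
  conditions.py         the four reference constructs + theoretical rate
  config.py             YAML (de)serialization
  cli.py                simulate / generate / fit / report subcommands
docs/methods.md         model, assumptions, numerical choices, limitations
```
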