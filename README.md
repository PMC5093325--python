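# peptube

Growth and shrinkage kinetics of supramolecular peptide filaments.

Self-assembling dipeptides such as diphenylalanine (FF, nanotubes in
water) and its cyclic derivative cyclo-Phe-Phe (cycloFF, needles in DMSO)
form dynamic one-dimensional assemblies whose length can be steered by the
free-monomer concentration around them: in a microfluidic flow reactor,
co-flowing a subcritical and a supercritical solution programs the
in-channel concentration and with it whether individual filaments grow,
hold, or shrink to dissolution. `peptube` packages the quantitative
machinery of that kind of single-filament study for people analysing (or
simulating) such experiments:

* the **linear growth law** `R(c) = k_on·c − k_off` and its zero, the
  critical concentration `c_s = k_off/k_on`; least-squares estimation of
  `(k_on, k_off)` with standard errors and a delta-method CI for `c_s`;
* an exact **kinetic Monte Carlo simulator** of a two-ended filament with
  independent per-face rates, optional irreversible capping, an open
  (constant-concentration flow) bath or a closed, mass-conserving monomer
  pool that equilibrates at `c_s`;
* a **synthetic observation layer** emulating the microscopy protocol
  (frame sampling, five replicate reads averaged per time point);
* a per-terminus **directionality classifier** (unidirectional vs
  bidirectional growth — strongly asymmetric faces, as in FF, grow at one
  end only; symmetric ones, as in cycloFF, at both);
* the **co-flow mixing arithmetic** (flow-weighted mean, unit-tagged
  mg/ml ↔ mM conversion, inverse flow-split solver).

See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

Five concentrations spanning sub- to supercritical, ten tubes each,
simulated, frame-sampled with replicate-averaged measurement noise, and
pushed through the whole estimation chain:

```python
from peptube.synthetic import ExperimentDesign
from peptube.pipeline import run_recovery

report = run_recovery(ExperimentDesign.ff_default(master_seed=42))
print(report.summary())
```

prints

```
Growth-law recovery report
--------------------------
conditions: 5  tubes: 50
k_on  = 3.259 +/- 0.089 um/min/mM
k_off = 7.211 +/- 0.2 um/min
R^2 = 0.9978
critical concentration = 2.21 mM (95% CI 2.17-2.26)
directionality tally: {'unidirectional': 50, 'bidirectional': 0, 'stalled': 0, 'indeterminate': 0}
```

The generating truth was `k_on = 3.36`, `k_off = 7.4` (so `c_s = 2.20`
mM): both parameters sit inside their 95% intervals, the fitted line
crosses zero at the true critical concentration, and every strongly
asymmetric tube is correctly called unidirectional. The
`examples/` directory holds one short script per capability
(mixing arithmetic, growth-law fitting, open-bath simulation, closed-pool
equilibration, the recovery experiment above), each printing the numbers
it computes and what they mean.

A thin CLI mirrors the library:

```sh
peptube simulate --preset ff --mode open --conc 3.2 --tmax 10 --seed 1 --out trace.csv
peptube observe --trace trace.csv --seed 2 --out obs.csv
peptube rates --traces obs.csv
peptube mix --config mix.yaml
peptube recover --config design.yaml --out report.json --text
```

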