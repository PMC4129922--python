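# tumoropt

Simulator and optimal-control toolkit for an 11-compartment tumor–immune
interaction model with immunosuppression (regulatory T cells, TGF-β, IL-10)
and two therapies: chemotherapy (drug concentration `M`) and immunotherapy
(direct CD8⁺ T-cell injection).

The package provides:

- **`tumoropt.model`** — the state layout `(T, N, ET, DU, DL, HT, GT, S, I2,
  I10, M)`, the model right-hand side, reference initial conditions, and
  unit-conversion helpers.
- **`tumoropt.params`** — the full parameter set with reference defaults
  (shipped as `tumoropt/data/parameters.yaml`), YAML/JSON (de)serialization,
  and the immunosuppression on/off switch (which zeroes
  `alpha3, gamma2, p1, p2, p3, p4` and the suppressive initial state).
- **`tumoropt.simulate`** — fixed-step RK4 integration under bolus/continuous
  therapy schedules, and the four reference regimes (`none`, `immunotherapy`,
  `chemotherapy`, `combined`; 2.3869 mg/L drug and 1.77×10¹⁰ cells/L CD8
  boluses every 21 days).
- **`tumoropt.control`** — the quadratic-cost optimal control problem
  (`∫ A·T + B·uE² + C·uM² dt`, controls bounded in [0, 1]): Hamiltonian,
  machine-generated costate system (exact negative state-gradient, see
  `tools/gen_adjoint.py`), clipped-quadratic control characterization, a
  relaxed forward–backward sweep solver, and a costate-vs-finite-difference
  gradient check.
- **`tumoropt.sensitivity`** — one-at-a-time ±20% parameter perturbation with
  a 5-day tumor-size readout and ranking.
- **`tumoropt.cli`** — the `tumoropt` command-line entry point.

The kill-term suppression constant `s1` has no published value; it defaults
to the TGF-β half-saturation used for proliferation suppression (`s2`,
580 000 IU/L) and can be overridden in any parameter file.

## CLI

```sh
# fixed therapy protocol
tumoropt simulate --regime combined --t0 1e8 --horizon 100 --step 0.01 \
    --suppression on --out traj.csv --plot traj.png

# optimal control (CSV + JSON diagnostics sidecar)
tumoropt optimize --t0 1e7 --weights 1,10,1000 --suppression on --tf 50 \
    --out solution.csv --plot controls.png

# one-at-a-time sensitivity
tumoropt sensitivity --t0 1e7 --days 5 --out sens.csv --plot tornado.png

# every reference scenario + summary report
tumoropt reproduce-all --outdir report/
```

All outputs embed the resolved configuration (a `#`-prefixed JSON header in
CSVs, a JSON sidecar for solver runs), and identical configurations produce
bit-identical files. Use `--params my_overrides.yaml` to override any subset
of parameters.

## Regenerating the costate module

`src/tumoropt/_adjoint.py` is generated (sympy differentiation of the
implemented Hamiltonian + common-subexpression elimination). After any change
to the model right-hand side, rerun:

```sh
python tools/gen_adjoint.py
```
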