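# pclattice

Numerical analysis of a bistable lattice of hierarchically coupled
neural-mass layers with predictive-coding feedback: each layer receives an
instantaneous feedforward drive, a feedforward error correction, and a
feedback error correction, all through a logistic activation
`S(x) = 1 / (1 + exp(-mu (x - theta)))`.

The package provides:

* **nonlinearity** — the logistic activation, its derivatives and inverse
  (overflow-safe, guarded inversion).
* **equilibria** — homogeneous equilibrium branches (down / middle / up),
  fold points `x_*(mu) = 1/2 ∓ sqrt(1/4 - 1/mu)`, the bistable parameter
  window, and the linear-stability spectrum of each branch.
* **lattice_model** — right-hand sides of every model variant: the scalar
  three-point coupling map, the finite hierarchy with input/top closures, the
  clamped truncation of the bi-infinite lattice, the d-population matrix
  model, diagonal-weight and spike-frequency-adaptation extensions.
* **simulate** — input protocols (constant, flashed), step initial
  conditions, adaptive time integration, and named scenario presets.
* **waves** — traveling-front speed estimation from step initial data
  (least-squares fit of the tracked interface), pinning detection
  (propagation failure), co-moving profile extraction, and sign maps of both
  wave speeds over parameter grids.
* **thresholds** — semi-infinite network experiments in both orientations
  (input below: bottom-up; input above: top-down): outcome classification
  (stagnation, front / stacked / pulse propagation, propagation failure),
  bisection for the critical input amplitude `s0*`, the critical flash
  duration `tau*`, and the pinning-region boundaries `q0` / `theta0`, plus
  joint regime maps.
* **cli_io** — a `pclattice` command-line tool wrapping all of the above
  with JSON/CSV outputs and reproducibility manifests.

## CLI

```sh
pclattice simulate --preset fig2a --out out/            # scenario preset
pclattice simulate --config run.json --out out/         # custom run
pclattice branches --theta 0.5 --mu 16
pclattice speed --theta 0.5 --mu 16 --p 0.1 --q 0.6 --direction ud
pclattice signmap --q 0:0.9:19 --theta 0.3:0.7:21 --out out/
pclattice threshold-s0 --theta 0.35 --q 0.35 --direction up
pclattice threshold-tau --theta 0.45 --q 0.3 --direction up
pclattice pinning-boundary --theta 0.35 --q 0.65 --free theta --direction up
pclattice regime-map --theta 0.35 --out out/
```

Layer convention: the input layer is lattice index 0; bottom-up layers are
positive, top-down layers negative.  Every CLI run writes a `manifest.json`
sufficient to reproduce it bit-identically.

A config file is JSON with keys
`{theta, mu, p, q, J, t_final, output_dt, protocol: {kind, s0, tau},
initial: {direction, interface_index}, solver: {rtol, atol}}`.

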