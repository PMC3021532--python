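# loopdose

Dynamic-hysteresis and dose-effectiveness analysis of a tumor–immune growth
model under periodic therapy.

The model couples logistic tumor growth with a saturating immune predation
term,

```
dx/dt = a*x*(1 - b*x) - beta*x^2/(eps + x^2) - c(t)
```

where `c(t)` is a periodic therapy pulse train (rectangular or half-sine,
amplitude `h0`, period `T`, duty cycle `d`), entering either additively
(`c = h(t)`, the default) or multiplicatively (`c = h(t)*x`, proportional
kill). The pipeline:

1. **simulator** — integrates each `(h0, d)` cell to its steady periodic
   orbit, splitting every cycle at the waveform discontinuity.
2. **loop_analytics** — measures the hysteresis loop of density against
   intervention: loop area `S` (shoelace rule), per-cycle dose `I`,
   cycle-average density and excursion, plus flat-tail features of the
   dose–effect curve (optimal dose, effective duty cycle).
3. **scaling_collapse** — forms the therapy-effect matrix `Y = S/h0` over
   the amplitude × duty-cycle grid, max-normalizes each amplitude series to
   `(I', Y')`, pools the points, and fits the quadratic law
   `y = m*x^2 + n*x` through the origin.
4. **fixtures** — synthetic loops, surfaces and curves with embedded ground
   truth (closed-form ellipse areas, known quadratic laws, sigmoid onsets),
   so every stage is testable without integrating the ODE.

## CLI

```sh
loopdose simulate --h0 0.5 --d 0.5 --out cycle.csv     # one steady cycle (t,x,h)
loopdose analyze  --cycle cycle.csv --out record.json  # per-cycle observables
loopdose sweep    --config cfg.toml --out surface.csv  # full (h0 x d) sweep
loopdose collapse --surfaces surface.csv --out collapse.json --reduced-out reduced.csv
loopdose fixtures make --kind ellipse_loop --params '{"h0":1,"x0":2,"phi":1.5708,"c":3}' --out fx.csv
loopdose run-all  --out results/                       # sweep both waveforms + collapse
```

All commands refuse to overwrite existing outputs unless `--force` is
given. Every CSV gets a JSON sidecar carrying the full configuration, so a
run is reproducible bit-for-bit from its outputs. Config files are TOML or
YAML with `[model]`, `[intervention]`, `[grid]`, `[solver]` sections; all
values default to the canonical parameter set (`a=1, b=0.1, beta=1, eps=1`,
grids `h0 = 0.1..1.0`, `d = 0.1..0.9`).

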