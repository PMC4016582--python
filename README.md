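# divcontrol

Is bacterial division triggered by a **timer** (a cell divides after a
certain time since birth) or a **sizer** (a cell divides upon reaching a
critical size)?  `divcontrol` implements the quantitative machinery needed
to discriminate between the two hypotheses from single-cell lineage data:
exact stochastic simulation of growing and dividing lineages, nonparametric
estimation of the division rate, deterministic solvers for the
structured-population (growth–fragmentation) equations, and a normalized-L²
goodness-of-fit distance with robustness analyses.

It is aimed at quantitative microbiologists and modellers working with
time-lapse single-cell data — agar-pad microcolonies (full genealogical
trees, every descendant followed) or mother-machine microfluidics (sparse
trees, one daughter followed per division).

## The models

The density n(t, a, x) of cells of age *a* and size *x* obeys the
age-and-size-structured equation

    ∂ₜn + ∂ₐn + ∂ₓ(v(x) n) = −B(a, x) n,
    n(t, 0, x) = 4 ∫ B(a, 2x) n(t, a, 2x) da        (full tree)

where v(x) is the single-cell growth law (exponential, v·x, over a central
size range, with configurable caps outside it) and B is the division rate
(hazard): **timer** means B = B_a(a), **sizer** means B = B_s(x).  After
transients, n(t,a,x) ≈ e^{λt} N(a,x) with Malthus coefficient λ and stable
distribution N.  For sparse trees the renewal factor 4 becomes 2 and λ ≈ 0.

The division rates are estimated nonparametrically from tracked cycles by
occurrence/exposure (survival-hazard) estimators,

    B̂_a(a) = f̂(a) / Ŝ(a),        B̂_s(x) = v(x) ψ̂(x) / π̂(x),

with f̂, ψ̂ kernel densities of ages/sizes at division, Ŝ the smoothed
survival and π̂ the at-risk fraction.  Model fit is scored by
D = sqrt(∬(f−g)² / ∬f²) between the empirical age–size distribution
(kernel estimate of every cell at every time step) and the model's stable
distribution; D is reported in percent.

## Worked example

```python
from divcontrol import EvalConfig, evaluate_models, simulate_mother_machine
from divcontrol.presets import sim_preset

# ~9,500 complete cycles of sizer-controlled growth in a mother machine
cfg = sim_preset("sizer-s1", seed=1, generations=50, n_channels=250)
tracks = simulate_mother_machine(cfg)

report = evaluate_models(tracks, EvalConfig(topology="sparse_tree",
                                            generation_window=(10, 50),
                                            n_perm=1000, seed=1))
print(f"D_age  = {report.d_age.percent:.1f}%")
print(f"D_size = {report.d_size.percent:.1f}%")
print(f"r(age at division, size at birth) = {report.correlation_r:.2f}")
print(f"preferred model: {report.preferred}")
```

Output:

    D_age  = 109.3%
    D_size = 9.9%
    r(age at division, size at birth) = -0.69
    preferred model: sizer

The sizer model reconstructs the empirical age–size distribution to within
~10%, while the best timer fit misses it by a factor ten; the strong
negative correlation between size at birth and age at division (cells born
large divide sooner) independently rules out a pure timer.  Running the
same pipeline on timer-generated tracks prefers the timer model, so the
discrimination is symmetric.

The same stages are available from the shell:

    divcontrol simulate --preset sizer-s1 --seed 1 -o tracks.csv
    divcontrol pipeline -i tracks.csv --sparse-tree -o report.json
    divcontrol robustness-scan --noise septum --cv 0.05,0.1,0.2 -o scan.csv

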