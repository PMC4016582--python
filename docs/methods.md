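# Methods

## Models

Two classical structured-population models describe a proliferating
bacterial population.  Under **timer** control the division rate depends on
cell age only, B = B_a(a); the age density obeys the McKendrick–von
Foerster equation with renewal boundary n(t,0) = 2∫B_a n da.  Under
**sizer** control the rate depends on size only, B = B_s(x); the size
density obeys the growth–fragmentation equation
∂ₜn + ∂ₓ(v n) = −B_s n + 4 B_s(2x) n(2x), where the factor 4 encodes
binary fission into two daughters of half size.  Both are restrictions of
the two-dimensional age-and-size equation, which is what the solver always
integrates so that the joint distribution N(a,x) and both marginals are
available.  In the stable regime n ≈ e^{λt} N; λ is the Malthus
coefficient.  Two exact consequences serve as solver oracles: a constant
age hazard b forces λ = b with N(a) = 2b·e^{−2ba}, and pure exponential
growth v(x) = v·x forces λ = v because fragmentation conserves biomass.

For mother-machine (sparse-tree) data only one daughter is followed per
division; the renewal factors drop from 4 to 2 (two-dimensional and size
equations; the size Jacobian survives, the number doubling does not) and
from 2 to 1 (pure age equation), and λ ≈ 0.  This is our derivation of the
"one daughter followed" bookkeeping; it is validated against the
mother-machine simulator.

**Growth law.** v(x) = v·x on a central range [x_min, x_max]; outside, the
behaviour of rare small/large cells is unknown and is replaced by a cap:
constant rate (linear growth), an affine continuation, or a cubic
polynomial p(x) clamped at zero.  Two published example parameterizations
ship as presets (`f1`: v = 0.0274 min⁻¹, range [2.3, 5.3] µm,
p(x) = −0.0033x³ + 0.036x² − 0.094x + 0.13; `s1`: v = 0.0317 min⁻¹,
[3.5, 7.2] µm, p(x) = −0.0036x³ + 0.063x² − 0.33x + 0.67).  A timer
population only has a stable size distribution because of these caps —
under uncapped exponential growth the size distribution never settles,
which the solver reports as an error (see *Numerics*).

## Stochastic simulator

The simulator is the Monte-Carlo ground truth for the solvers and the
synthetic stand-in for experimental track tables.  Each cell draws an
individual growth rate v_i from a truncated Gaussian (mean v, CV 8% by
default, truncated at ±3 SD and at 0.2·v), grows deterministically along
the scaled law (v_i/v)·v(x), and divides by exact inversion of the
survival function exp(−∫B dt): closed-form table inversion for timer
hazards and for sizer hazards under exponential growth (change of variables
to ∫B(s)/s ds), numeric integration along the trajectory otherwise.  At
division a septum ratio θ is drawn from a truncated Gaussian about 1/2
(CV 4% by default, truncated to (0.2, 0.8)); daughters receive θ·x_d and
x_d − θ·x_d, so birth lengths partition the mother's length to rounding
precision.  Growth rates are i.i.d. across cells (no mother–daughter
correlation), matching the inheritance assumption of the growth-rate
noise-extended model.

**Observation convention.**  Lengths are recorded on a per-cell frame grid
(2 min for the agar-pad condition, 1 min for the mother machine) anchored
at birth, and the realized division age is the continuously sampled age
rounded to the nearest frame (minimum one frame).  This is the only
convention under which constant frame spacing, the exact mass partition
and septum ratios summing to one can all hold in the rendered table, and
it reproduces the experiments' time-resolution limit (the acquisition step
is 5–8% of a division time).  Rounding to nearest keeps division-age
statistics unbiased to first order.

Full-tree founders start staggered uniformly over one doubling time, as in
a real inoculum.  Without staggering the colony "rings" coherently at the
generation period for roughly ten generations (single-cycle duration CVs
of 15–25% desynchronize cohorts slowly), which visibly contaminates
time-pooled distributions.  Mother-machine channels are asynchronous by
construction.  Random numbers come from per-generation streams derived
from the root seed (`numpy` SeedSequence spawn keys) with cells processed
in a canonical order, so identical (configuration, seed) gives a
byte-identical table and tree-traversal order cannot influence results.

**Default study conditions.**  Mean growth rates, frame intervals,
growth-rate CV (8%) and septum CV (4%) follow the two experimental
conditions above.  The sizer preset hazard is B_s(x) = 0.02·(x/3)⁸ min⁻¹
(division sizes concentrated near 4 µm, births near 2 µm, ~25 min cycles).
The timer preset hazard is Weibull with shape 5 and mean division age
27.5 min (CV ≈ 23%, within the 0.2–0.35 range reported for *E. coli*
cycle times).  With the `f1` growth rate this sets v·T slightly above
ln 2, so timer homeostasis is genuinely maintained by the growth caps;
this is the regime in which the timer model is meaningful at all, and the
regime in which its sensitivity to the cap assumptions (see below) is
visible.  Full-tree analyses discard the first 150 min of the record;
mother-machine analyses keep generations 10–50.

**Measurement layer.**  Length noise is multiplicative, (1+ε) with ε a
Gaussian truncated at ±4 SD.  Division-time noise shifts each division
event by a Gaussian offset with SD = CV × mean cycle duration, snapped to
the frame grid, and reattributes the boundary frames between mother and
daughters (the mother's continued length is the daughters' sum, or the
followed daughter's length divided by its septum ratio in sparse trees) —
i.e. misdetection of the septum by a few frames.  Offsets a cycle cannot
accommodate are redrawn; if more than 1% of cycles cannot accommodate
their first-draw offset the requested noise level is rejected.  Note that
the *division-time* error has the stated SD; the *division-age* error
carries √2 times it, because both endpoints of a cycle shift.

## Density estimation

Age, size and age–size distributions are Gaussian-kernel estimates on
uniform cell-centered grids (2⁷ nodes per axis by default), computed by
binned convolution, with mass reflected at the zero boundary.  Bandwidths
follow Silverman's rule (1-D) and Scott's rule per axis (2-D).  Two
refinements matter for this data type:

* **Lattice samples.**  Division ages and occupation ages live on the
  acquisition lattice.  The kernel for such samples is the Gaussian
  convolved with a box of exactly one frame width (closed form via the
  integrated normal CDF): the box matches the frame-rounding error and its
  spectral zero removes the comb artifact that a plain kernel produces,
  without the bias of simply inflating the bandwidth.
* **Survival functions.**  The survival Ŝ entering the age hazard is the
  closed-form CDF of the kernel estimate evaluated directly on the sample,
  not a numerical integral of the gridded density: grid quadrature of a
  density with boundary mass is biased at the few-per-mille level, which
  the hazard amplifies wherever survival is small.

The empirical age–size distribution is the kernel estimate of the
*occupation measure*: every retained cell at every frame.  A dividing
cell's final frame is excluded (at that timestamp its daughters, at age
zero, have replaced it in the population), and a lattice age stands for
the age interval up to the next frame, so the age coordinate is shifted by
half a frame and convolved with the one-frame box.

## Division-rate estimation

Both estimators are occurrence/exposure constructions: B̂_a = f̂/Ŝ with
Ŝ ≥ s_min (default 0.02), and B̂_s = v·ψ̂/π̂ with the exact empirical
at-risk fraction π̂(x) = #{x_b ≤ x < x_d}/n ≥ p_min (default 0.02).
Outside the reliable support the rate continues as a constant (so the PDE
solvers receive a finite hazard everywhere); below the smallest birth size
it is zero; the reliability mask records the affected range.  These
estimators are consistent for the respective models without any
genealogical weighting, because conditional on being at risk the hazard is
identical on every branch — full-tree and sparse-tree data are treated
identically.  Right-censored (incomplete) cycles are excluded, with a
warning when they exceed 10%.

## Numerics

First-order upwind finite volumes on uniform cell-centered grids.  The
time step follows the transport CFL bound
dt = safety/(max v·n_x/X_max + n_a/A_max) with safety 0.9 (0.45 in the
high-accuracy closed-form checks); the division loss term is implicit
(divide by 1 + dt·B), so arbitrarily steep hazards never constrain the
step.  In the two-dimensional solver, age advection runs at unit Courant
number — an exact one-cell shift per macro step of length da, with the
size transport and loss in CFL-limited substeps and newborns accumulating
continuously in the emptied age-0 cell.  This removes upwind age
diffusion entirely and gives each age cell exactly the ages
(i·da, (i+1)·da]; with it, the constant-hazard closed form is reproduced
to an L¹ error of ~10⁻⁴ on a 256-cell age grid.  The fragmentation gain
at 2x is evaluated by linear interpolation (zero beyond the grid), the
density is renormalized to unit mass at every step, λ is the mean
per-step log growth over the last 100 steps, and iteration stops when the
sup-norm change falls below 10⁻⁸.

A converged iterate is accepted only if the renewal and transport fluxes
lost at the size boundary are below `leak_tol` (default 10⁻³ of the
division flux).  A state that is stationary only because mass escapes at
X_max — the numerical signature of timer control under uncapped
exponential growth, which provably has no stable distribution — is
reported as "no stable distribution reached", with the last iterate
attached for inspection.

The noise-extended sizer models share this machinery: growth-rate
variability adds a rate axis (100 grid points spanning [0.9·v_min,
1.1·v_max]) with newborns redistributed over rates i.i.d. from the rate
density; septum noise replaces the 2x gain by the kernel integral
2∫B(y)q(x/y)n(y)/y dy, discretized as a matrix with columns renormalized
to inject exactly two daughters (one, for sparse trees) per division.

## Model comparison

D = sqrt(∬(f−g)²/∬f²), with the empirical density f as reference, by
trapezoidal quadrature; for isotropic bivariate Gaussians with SD ratio α
this equals sqrt(1 + 1/α² − 4/(1+α²)) — 15.7% at α = 0.9 and 46.7% at
α = 0.75 — which calibrates the scale of reported values.  Because a
kernel estimate targets the smoothed density K_h∗f, model predictions are
convolved with the estimator's own kernel before distances are taken;
without this, differential smoothing of sharp features (the sizer stable
distribution has kinks at half the division sizes) dominates the
comparison.

`evaluate_models` runs the full chain: cycle extraction → growth analysis
(per-cell log-OLS exponential rates; binned increment curve; detection of
[x_min, x_max] where the increment deviates from proportionality by more
than 2 SEM plus a 2% relative floor; cubic cap fit) → hazard estimation →
stable distributions under the timer restriction (capped growth law built
entirely from the increment curve — its proportional slope gives the core
exponential rate, since per-cell OLS rates are biased low when cells dwell
in the capped ranges) and the sizer restriction (pure exponential at the
mean per-cell rate) → distances, correlation diagnostic (Pearson r of
division age vs birth size with a seeded permutation p-value), preferred
model = argmin(D_age, D_size).  A restriction whose iteration does not
stabilize is scored on its last iterate and flagged unconverged.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the method consumes:
genealogy topologies, frame-quantized exponential growth with realistic
rate and septum variability, hazard-driven division, measurement noise.
It does not emulate segmentation artifacts, width dynamics, filamentation,
replicative aging, or day-to-day condition drift, and its hazards are
smooth parametric shapes rather than whatever *E. coli* implements.
Passing tests therefore demonstrate the *method* — estimator consistency,
solver correctness, discrimination power at realistic noise and sample
sizes — not biological conclusions about real strains.

Study sizes used in the automated checks (chosen to give comfortable
Monte-Carlo margins): 2×10⁴ cycles for hazard recovery (error < 15%, and
decreasing in median over 10³–10⁵ cycles); ≥5×10⁴ observations for the
PDE-vs-simulation agreement (D < 5%, at the 1-min acquisition channel,
where frame-rounding contributes least); ~10⁴ cycles per replicate for
the discrimination (10/10 correct in both directions).

## Known limitations

* First-order spatial accuracy in size: Malthus coefficients carry
  O(dx) errors (~0.4% at 256 cells for the steep preset hazard); the
  closed-form checks use 256–384 size cells.
* The survival-hazard estimators are biased near the edges of the
  reliable support (smoothing over a steep hazard); the constant
  continuation beyond it is a modelling choice, with a power-law
  alternative left to the caller.
* The distance compares kernel-smoothed objects; with very small samples
  the smoothing term, not the model mismatch, can dominate D.
* Division-time measurement noise reattributes whole frames, so its
  granularity is the acquisition step.
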