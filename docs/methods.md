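# Methods

## The scientific problem

During sustained exocytosis in chromaffin cells, release events detected
by amperometry form a point process whose statistics carry information
about how vesicles travel from the reserve pool to the plasma membrane.
Two hypotheses make sharply different predictions:

* **purely diffusive transport** — arrivals at the membrane are maximally
  random; interspike times are exponential, window counts Poisson, and
  the count dispersion index σ²/μ equals 1;
* **membrane-directed transport** — arrivals are partly deterministic;
  interspike times follow a two-parameter gamma distribution with shape
  p > 1, counts follow the gamma-count distribution, and σ²/μ < 1.

The package implements both halves of the argument: a Langevin simulator
that turns a transport hypothesis into a release train, and a
renewal-statistics pipeline that turns any release train (simulated,
synthetic or experimental) into fitted model parameters.

## Point-process pipeline

**Spike sequences.** Ordered event times on (0, T].  Interspike times
δt_i = t_{i+1} − t_i and window counts are the two complementary views of
the process.  Trailing partial count windows are discarded so counts are
identically distributed; duplicate event times are rejected (amperometric
peaks are resolvable).

**Rate estimation (density-function method).** λ(t) = Σ_n ω(t − t_n)
with ω a unit-mass Gaussian kernel.  The default kernel standard
deviation is **10 s**: experimental-scale trains run at ~0.6–2.5 Hz for
hundreds of seconds, so a 10 s kernel averages ≈ 6–25 spikes — wide
enough to suppress single-spike granularity, narrow enough to track a
plateau-plus-decay profile with a ~100 s-scale transition.  No boundary
correction is applied; the only normalization defect is kernel mass
leaking past 0 and T, so ∫λ ∈ [0.95 N, N] for interior-supported trains.
The grid step defaults to bandwidth/10.

Bandwidth sensitivity: rescaling a train by its own kernel estimate
mildly *regularizes* the rescaled intervals, because the estimate tracks
local clustering.  At n = 900 and bandwidth 10 s this inflates a fitted
gamma shape of 1.6 by ≈ +0.1 (cross-seed mean 1.67); at bandwidth 50 s
the inflation essentially vanishes.  We keep 10 s as the default because
real decaying rates need the tracking; the bias is reported here rather
than hidden.

**Time rescaling.** Λ(t) = ∫₀ᵗ λ; τ_i = Λ(t_i), u_i = Λ_{t_{i−1}}(t_i).
Λ is evaluated exactly for the piecewise-linear interpolant (trapezoid on
segments) and inverted exactly per segment (quadratic solve), so
rescale ∘ inverse-rescale is an identity to round-off, which the
synthetic generator exploits.  A rate that vanishes on an interval
carrying spikes is rejected as degenerate rather than silently collapsing
intervals.

**Logistic rate model.** r(t) = r0/(1 + e^{−β_r(t−μ_r)}) + rf.  With
β_r < 0 this is a plateau (r0 + rf) decaying to rf with midpoint μ_r —
the shape of ex-vivo recordings.  The sign of β_r is left free and the
fit starts deterministically (amplitude from the range, midpoint at the
half-range crossing, sign from the end-to-end slope) because the logistic
is multimodal in its parameters.

**Histograms and fits.** Interspike bin width h = (μ + 2.85σ)/√N for
N < 1000 and the scaled Scott's rule (μ + 2.85σ)(1/(2√N) + 1/(2N^{1/3}))
for larger samples; count window ΔT = 4μ for raw trains and τ̄ = 4.0 for
rescaled ones.  Candidate families: exponential/Poisson and
gamma/gamma-count (log-normal available).  The gamma-count pmf
P(k) = G(pk, βT) − G(pk+p, βT) uses the regularized lower incomplete
gamma with the convention G(0, x) := 1, which is what makes Σ_k P(k) = 1
and the p = 1 Poisson reduction exact.  Fits minimize the SSE of the pdf
at bin centers (pmf at integer counts) against probability-normalized
histograms, with moment-based starts; empty bins stay in the SSE.  A
combined fit sharing one parameter set between the interspike and count
histograms (β = 1/θ) is provided and used for end-to-end recovery, where
the count term stabilizes the shape estimate.  R² = 1 − SSE/SST, clamped
at 0 with a flag.  Maximum-likelihood fitting is deliberately *not* the
reported route (the printed parameters this package mirrors come from
histogram least squares); it appears only as a cross-check oracle in the
tests.  Note the gamma-count pmf describes an ordinary renewal process
(fresh interval at the window start); stationary windows of the same
train have a slightly different mean (≈ (CV²−1)/2 counts), which matters
when validating against simulation.

## Langevin simulator

Hard-sphere vesicles (radius 150 nm) move by overdamped Euler–Maruyama
dynamics in a 4.4 × 1 × 4.4 μm box: five hard walls and one absorbing
face (the membrane, plane y = 0).  Default physical parameters:
D = 3.22e-14 m²/s, T = 296 K, density 2.09 μm⁻³ (→ n = 40 vesicles).
Absorbed vesicles are replaced at a random position so n stays constant;
hit times form the release train.  An optional harmonic force
F_y = −α(y − y0) (zero lateral components) models directed transport.

Numerical choices: dt = 1 ms (rms step ≈ 8 nm ≪ radius; a validity check
rejects dt with √(2D dt) ≥ radius/3); overlap resolution pushes each
overlapping pair apart symmetrically along its center line to contact
distance, iterated up to 10 sweeps ("elastic" collisions in an overdamped
setting mean non-penetration, not momentum exchange); multiple hits in
one step get evenly spaced sub-step timestamps so event times are
strictly increasing; the inner loop is numba-compiled and bitwise
reproducible for a fixed seed.  Internal units are μm and s; configs are
SI.

### Conventions and the absolute time scale

The reference Langevin formulation relates the noise coupling σ,
friction γ and D inconsistently (σ² = 2k_BTγ alongside D = 2k_BTγ cannot
both hold and the latter is not even dimensional), so the simulator
exposes the choice:

* `noise_convention="standard"` — per-axis step variance 2·D·dt, drift
  mobility D/k_BT (fluctuation–dissipation consistent; the default);
* `noise_convention="literal"` — per-axis variance D·dt, mobility
  D/(2k_BT): the literal reading σ/γ = √D.

Boundary handling: `boundary="sphere"` (walls inset by one radius, hit
when the center comes within one radius of the membrane plane) or
`"point"` (walls and membrane applied to centers).  Replacement:
`"uniform"` in the volume, `"faces"` (a random point on the five hard
faces — re-entry *through* the walls), or `"far_wall"`.

These choices fix the absolute time scale of the event train, and a 1D
mean-first-passage calculation makes the effect exact: for one vesicle
with effective diffusion D_eff on an interval of length L_eff (absorbing
at one end, reflecting at the other), the uniform-restart mean interval
is L_eff²/(3D_eff), and the pooled mean interspike time of n independent
vesicles is that divided by n.  With the physically standard conventions
(2D dt, inset walls, uniform replacement) the free-Brownian pooled mean
is 0.127 s.  The literal-equation noise (D_eff = D/2), point-center
boundaries (L_eff = 1 μm) and face re-entry (area-weighted mix of
uniform-height and far-wall starts) give 0.65 s — which is what the
built-in experiment configs use, and within 5 % of what the full
simulator then actually produces (0.59 s once hard-sphere crowding and
the ~15 % of face entries that start near the membrane are included).
The reconstruction was chosen once, from this calculation, as the
experiment-level default; the library default stays physical.

### Known limitation: the harmonic runs

Two structural facts mean the harmonic-potential experiment cannot
reproduce gamma-shaped pooled statistics from its printed parameters:

1. **The printed α is dynamically inert.**  α = 1.275e-13 N/m with any
   dimensionally consistent mobility gives a drift relaxation rate
   α·D/k_BT ≈ 1.0e-6 s⁻¹ — nine orders of magnitude too slow to matter
   during a ~30 s membrane transit.  Equivalently, the potential depth
   across the whole 1 μm box is ~1.6e-5 k_BT.  The simulator implements
   the force faithfully and reports the relaxation rate in the config
   snapshot; it does not silently rescale α.
2. **Pooling erases per-vesicle regularity.**  The event train is a
   superposition of n = 40 independently cycling vesicles (each
   absorption triggers only that vesicle's replacement).  By the
   Palm–Khintchine superposition theorem the pooled train converges to
   Poisson regardless of how regular each vesicle's first-passage cycle
   is; at n = 40 and 3 % packing fraction the residual deviation is
   percent-level.  So a pooled gamma shape of ~1.6 would require either
   strong inter-vesicle coupling (a jammed membrane queue — not present
   at this density) or an effective ensemble of very few vesicles.

Consequently the harmonic experiment reproduces the *Brownian* statistics
(shape ≈ 0.93, dispersion ≈ 1), and the package treats the directed-
transport signature as a property the model class cannot generate at
these parameters, rather than forcing it.  The fusion-lag invariance —
the third headline claim — is independent of this and holds exactly as
expected.

## Fusion lags

Docking-to-fusion lags are sampled by inverse transform from a tabulated
pdf/cdf.  An empirical histogram is turned into a density by convolving
the piecewise-constant histogram with a Gaussian of sd = 0.2 × bin width
(exact block-wise convolution, support clipped at zero, renormalized).
The default parametric stand-in for the measured lag distribution — whose
histogram values are not published, only its support (~10–250 ms) and
mode (18 ms) — is a generalized-gamma with a = 1.5, c = 1, offset 10 ms,
scale 16 ms (mode 18 ms, mean 34 ms, <0.1 % mass beyond 250 ms); it is a
synthetic construction, labelled as such.  Lags may reorder events, so
release times are re-sorted; a telescoping argument bounds the mean-ISI
shift by (max lag)/(N−1) and i.i.d. lags inflate the interval variance by
≈ 2·Var(Δt_fus) — both asserted in the tests.

## Synthetic data

The generator emulates what the analysis assumes about real recordings:
gamma renewal structure (default shape 1.6), a logistic rate (defaults
r0 = 1.5 Hz, rf = 0.2 Hz, β_r = −0.02 s⁻¹, μ_r = 450 s → a ~1.7 Hz
plateau of roughly seven minutes, then an S-decay), 900 spikes, and
traces with 0.35 pA RMS noise (mid-range of the reported 0.2–0.5 pA)
at 2 kHz sampling.  Spike templates are instantaneous-rise, exponential-
decay (τ = 15 ms) — adequate for testing a detector keyed to amplitude,
not shape.  The detector smooths (2 ms moving average), subtracts a
block-median baseline, estimates the *raw* baseline RMS by MAD (so the
spikes themselves do not inflate it), and keeps local maxima above
3×RMS with ≥3 suprathreshold samples, merging runs closer than 50 ms so
noisy decay tails are not double-counted.

What the generator does **not** emulate: overlapping-spike shapes, foot
signals, quantal amplitude variation, electrode drift nonstationarity,
and any rate profile beyond logistic.  Passing tests therefore validate
the pipeline's statistical machinery, not the peak-shape preprocessing a
real recording needs before it becomes a spike sequence.

## Problem sizes

The experiment configs run the free-Brownian ensemble to 16 000 events
and the harmonic ones to 4 500 events (matching the reference run lengths);
replicate studies use 15 seeds.  Property tests use 10³–10⁵ draws where
a moment must be resolved, and the single-vesicle first-passage checks
use 2 500 events at dt and dt/2.
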