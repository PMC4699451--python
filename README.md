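# vesiflux

Stochastic simulation of vesicle transport to the plasma membrane, and
renewal-process statistics of exocytotic release events.

## The problem

During sustained exocytosis, each amperometric current spike marks the
fusion of one vesicle freshly arrived at the cell membrane, so the
sequence of spike times is a point process shaped by how vesicles travel
there.  If transport is pure diffusion, arrivals are maximally random:
interspike times δt are exponential, f(δt) = λe^{−λδt}, window counts
are Poisson, and the count dispersion index σ²/μ = 1.  If transport is
directed toward the membrane, the train is partly deterministic:
interspike times follow a two-parameter gamma distribution,

    f(δt; p, θ) = δt^{p−1} e^{−δt/θ} / (θ^p Γ(p)),   p > 1,

window counts follow the gamma-count distribution
P(k) = G(pk, βT) − G(pk+p, βT) with β = 1/θ and G the regularized lower
incomplete gamma, and counts are underdispersed (σ²/μ < 1).

`vesiflux` provides both sides of that comparison for researchers
working on regulated exocytosis and, more generally, on renewal
statistics of event trains:

* an overdamped **Langevin simulator** of hard-sphere vesicles in a
  sub-membrane box with an absorbing membrane face, constant ensemble
  size, and an optional harmonic attraction toward the membrane;
* a **statistics pipeline**: density-function rate estimation
  λ(t) = Σ ω(t − t_n), the time-rescaling transform
  τ = Λ(t) = ∫₀ᵗ λ (which maps trains with different, decaying rates
  onto comparable unit-rate trains), interspike and count histograms
  with sample-size-dependent bin widths, and least-squares fits of the
  exponential/Poisson versus gamma/gamma-count model pairs with R² and
  dispersion diagnostics;
* **docking-to-fusion lags** sampled by inverse transform from empirical
  or parametric distributions and superimposed on arrival trains;
* a **synthetic-data generator** (gamma renewal trains modulated by a
  logistic decaying rate; amperometric traces with a 3×RMS threshold
  spike detector) so the whole pipeline is testable end to end.

## Worked example

```python
import vesiflux as vf

# a synthetic sustained-release recording: 900 spikes, gamma shape 1.6,
# logistic rate (plateau ~1.7 Hz, S-shaped decay after ~7 min)
seq = vf.generate_inhomogeneous_sequence(p=1.6, n_spikes=900, seed=0)

rate = vf.estimate_rate(seq, bandwidth=10.0)
logistic = vf.fit_logistic_rate(rate)
rescaled = vf.rescale_sequence(seq, rate)

report = vf.model_report(rescaled.to_sequence(), count_window=4.0)
```

which prints, for this seed:

```
900 spikes over 1212 s
logistic rate: plateau 1.76 Hz, floor 0.17 Hz, midpoint 428 s
mean rescaled interval: 0.991
gamma fit: p = 1.70, theta = 0.60, R2 = 0.962
exponential fit: lam = 0.76, R2 = 0.796
count dispersion index: 0.49
```

Read: the estimated rate recovers the generator's logistic profile
(true midpoint 450 s); rescaling by the train's own rate gives unit-mean
intervals as the time-rescaling theorem demands; and the gamma model
(R² = 0.96) clearly beats the exponential one (R² = 0.80) on a train
built to be gamma with p = 1.6 — with underdispersed counts, the
signature of a partly deterministic release sequence.

The simulator is driven the same way:

```python
cfg = vf.brownian_config(seed=1)      # 40 vesicles, D = 3.22e-14 m^2/s
seq = vf.run_simulation(cfg)          # membrane-hit times
rep = vf.run_experiment("brownian", seed=1)   # sim + full analysis
```

A thin CLI wraps the same calls: `vesiflux run --experiment brownian
--seed 1 --outdir out/`, plus `simulate`, `synth`, `detect`, `fuse`.

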