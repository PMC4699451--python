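"""Overdamped Langevin simulator of vesicles in a sub-membrane cuboid.

Vesicles are hard spheres diffusing in a box with five hard walls and one
absorbing face (the plasma membrane at the plane y = y0).  Each membrane
hit is an exocytosis event; the absorbed vesicle is replaced at a random
position so the ensemble size stays constant, and the recorded hit times
form the release spike sequence.  An optional harmonic potential pulls
vesicles toward the membrane (F_y = -alpha (y - y0), zero lateral force).

Two conventions are supported for turning the diffusion coefficient into
a per-step noise amplitude, because the Langevin formulation this model
class circulates with relates the noise coupling sigma, the friction
gamma and D ambiguously (sigma² = 2 k_B T gamma alongside D = 2 k_B T
gamma cannot both hold):

``standard``
    per-axis displacement variance 2 D dt and Einstein mobility D/(k_B T)
    — the fluctuation–dissipation-consistent choice;
``literal``
    per-axis variance D dt and mobility D/(2 k_B T) — the literal reading
    of the noise coupling as sigma/gamma = sqrt(D).

Boundary handling is likewise configurable: ``sphere`` treats vesicles as
finite spheres (walls inset by one radius, hit when the center comes
within one radius of the membrane plane), ``point`` applies the walls and
the membrane to the centers.  See docs/methods.md for how these choices
shift the absolute time scale of the event train.

Config distances are SI metres; internally the simulator works in
micrometres and seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .sequences import SpikeSequence

__all__ = [
    "BOLTZMANN",
    "SimConfig",
    "EnsembleState",
    "initialize_ensemble",
    "harmonic_force",
    "step_overdamped",
    "reflect_and_resolve",
    "detect_and_replace",
    "run_simulation",
]

BOLTZMANN = 1.380649e-23  # J/K

_REPLACE_MODES = {"uniform": _kernels.REPLACE_UNIFORM,
                  "faces": _kernels.REPLACE_FACES,
                  "far_wall": _kernels.REPLACE_FAR_WALL}


@dataclass(frozen=True)
class SimConfig:
    """Physical and numerical parameters of one simulation (SI units in).

    Parameters
    ----------
    D : float
        Vesicle diffusion coefficient, m²/s.
    temperature : float
        Absolute temperature, K.
    radius : float
        Vesicle radius, m.
    box : tuple of float
        (L_x, L_y, L_z) in metres; the membrane is the face y = y0 = 0.
    density : float, optional
        Vesicle number density, m⁻³; n = round(density · volume).
    n_vesicles : int, optional
        Explicit ensemble size (overrides density).
    alpha : float
        Harmonic force constant toward the membrane, N/m (0 disables it).
    y0 : float
        Membrane plane coordinate, m (default 0).
    dt : float
        Euler–Maruyama step, s.
    stop_events, max_time : stopping criteria (events target / simulated s).
    seed : int
        RNG seed; fixed seed gives bitwise-identical event sequences.
    noise_convention : {"standard", "literal"}
    boundary : {"sphere", "point"}
    replacement : {"uniform", "faces", "far_wall"}
        Where an absorbed vesicle re-enters: uniformly in the volume, at a
        random point on the five hard faces, or on the face opposite the
        membrane.
    interactions : bool
        Hard-sphere overlap resolution on/off (off is a test hook for
        free-diffusion checks).
    membrane_reflecting : bool
        Test hook: make the membrane a reflecting wall (no absorption), for
        equilibrium checks under the harmonic potential.
    """

    D: float = 3.22e-14
    temperature: float = 296.0
    radius: float = 150e-9
    box: tuple = (4.4e-6, 1.0e-6, 4.4e-6)
    density: float | None = 2.09e18
    n_vesicles: int | None = None
    alpha: float = 0.0
    y0: float = 0.0
    dt: float = 1e-3
    stop_events: int = 16000
    max_time: float = 2.0e4
    seed: int = 0
    noise_convention: str = "standard"
    boundary: str = "sphere"
    replacement: str = "uniform"
    interactions: bool = True
    membrane_reflecting: bool = False

    def __post_init__(self):
        if self.D <= 0 or self.radius <= 0 or self.dt <= 0:
            raise ValueError("D, radius and dt must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if any(L <= 2.0 * self.radius for L in self.box):
            raise ValueError("box dimensions must exceed the vesicle diameter")
        if self.noise_convention not in ("standard", "literal"):
            raise ValueError("noise_convention must be 'standard' or 'literal'")
        if self.boundary not in ("sphere", "point"):
            raise ValueError("boundary must be 'sphere' or 'point'")
        if self.replacement not in _REPLACE_MODES:
            raise ValueError("replacement must be one of " + ", ".join(_REPLACE_MODES))
        if self.density is None and self.n_vesicles is None:
            raise ValueError("give either density or n_vesicles")
        if np.sqrt(2.0 * self.D * self.dt) >= self.radius / 3.0:
            raise ValueError(
                "dt too large: rms step sqrt(2 D dt) must stay below radius/3")
        n = self.n
        sphere_vol = 4.0 / 3.0 * np.pi * self.radius**3
        if n * sphere_vol >= 0.5 * self.volume:
            raise ValueError("infeasible packing: vesicles fill more than half the box")

    # --- derived quantities -------------------------------------------------
    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    @property
    def n(self) -> int:
        if self.n_vesicles is not None:
            return int(self.n_vesicles)
        return int(round(self.density * self.volume))

    @property
    def kBT(self) -> float:
        return BOLTZMANN * self.temperature

    @property
    def mobility(self) -> float:
        """Drift mobility 1/γ in m/(N·s), per the noise convention."""
        if self.noise_convention == "standard":
            return self.D / self.kBT
        return self.D / (2.0 * self.kBT)

    @property
    def drift_rate(self) -> float:
        """Harmonic relaxation rate k = alpha·mobility, s⁻¹."""
        return self.alpha * self.mobility

    @property
    def step_std_um(self) -> float:
        d_um = self.D * 1e12
        if self.noise_convention == "standard":
            return float(np.sqrt(2.0 * d_um * self.dt))
        return float(np.sqrt(d_um * self.dt))

    def _geometry_um(self):
        """(lo, hi, absorb_y) for the centers, micrometres."""
        L = np.asarray(self.box) * 1e6
        r = self.radius * 1e6
        y0 = self.y0 * 1e6
        if self.boundary == "sphere":
            lo = np.array([r, y0 + r, r])
            hi = np.array([L[0] - r, L[1] - r, L[2] - r])
            absorb = y0 + r
        else:
            lo = np.array([0.0, y0, 0.0])
            hi = np.array([L[0], L[1], L[2]])
            absorb = y0
        return lo, hi, absorb


@dataclass
class EnsembleState:
    """Vesicle center positions (micrometres) and the simulated time (s)."""

    positions: np.ndarray
    time: float = 0.0


def initialize_ensemble(config: SimConfig, seed: int | None = None) -> EnsembleState:
    """Uniform non-overlapping initial positions by seeded rejection sampling."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi, absorb = config._geometry_um()
    two_r = 2.0 * config.radius * 1e6
    n = config.n
    pos = np.empty((n, 3))
    for i in range(n):
        for attempt in range(10000):
            cand = lo + (hi - lo) * rng.random(3)
            if not config.membrane_reflecting and cand[1] <= absorb:
                cand[1] = absorb + (hi[1] - absorb) * rng.random()
            if not config.interactions or i == 0:
                break
            d = np.linalg.norm(pos[:i] - cand, axis=1)
            if np.all(d >= two_r):
                break
        else:
            raise RuntimeError("packing error: could not place vesicle without overlap")
        pos[i] = cand
    return EnsembleState(positions=pos, time=0.0)


def harmonic_force(position_um, config: SimConfig) -> np.ndarray:
    """Harmonic attraction toward the membrane, newtons.

    Zero lateral components; F_y = -alpha (y - y0) points toward the
    membrane plane for every y in the box (position given in μm).
    """
    pos = np.asarray(position_um, dtype=float)
    f = np.zeros(3)
    dy_m = (pos[1] - config.y0 * 1e6) * 1e-6
    f[1] = -config.alpha * dy_m
    return f


def _kernel_args(config: SimConfig):
    lo, hi, absorb = config._geometry_um()
    return dict(
        lo=lo, hi=hi, absorb_y=absorb,
        step_std=config.step_std_um,
        k_drift=config.drift_rate,
        y0=config.y0 * 1e6,
        dt=config.dt,
        two_r=2.0 * config.radius * 1e6,
        interactions=config.interactions,
        membrane_reflecting=config.membrane_reflecting,
        replace_mode=_REPLACE_MODES[config.replacement],
    )


def step_overdamped(state: EnsembleState, config: SimConfig, n_steps: int = 1,
                    seed: int = 0):
    """Advance the ensemble ``n_steps`` Euler–Maruyama steps.

    Returns ``(state, events)`` where ``events`` are the membrane-hit times
    (seconds) recorded during these steps.  Per axis the update is
    drift·dt plus noise of standard deviation ``step_std_um``; then wall
    reflection, overlap resolution, membrane detection and replacement.
    """
    args = _kernel_args(config)
    pos = np.ascontiguousarray(state.positions, dtype=np.float64)
    max_events = max(16, config.n * n_steps)
    events = np.empty(max_events)
    n_ev, t_end, unresolved, _ = _kernels.simulate_kernel(
        seed, pos, state.time, args["lo"], args["hi"], args["absorb_y"],
        args["step_std"], args["k_drift"], args["y0"], args["dt"], args["two_r"],
        args["interactions"], args["membrane_reflecting"], args["replace_mode"],
        max_events, n_steps, events)
    return EnsembleState(positions=pos, time=t_end), events[:n_ev].copy()


def reflect_and_resolve(state: EnsembleState, config: SimConfig) -> EnsembleState:
    """Reflect centers off the five hard walls and separate overlapping pairs.

    Overlapping pairs are pushed apart symmetrically along their center
    line to contact distance 2·radius (midpoint preserved), iterated for at
    most 10 sweeps.  Pure-python reference used by the tests; the kernel
    applies the identical rules inline.
    """
    lo, hi, absorb = config._geometry_um()
    pos = state.positions.copy()
    for i in range(pos.shape[0]):
        for ax in (0, 2):
            pos[i, ax] = _reflect_scalar(pos[i, ax], lo[ax], hi[ax])
        if config.membrane_reflecting:
            pos[i, 1] = _reflect_scalar(pos[i, 1], lo[1], hi[1])
        elif pos[i, 1] > hi[1]:
            pos[i, 1] = 2.0 * hi[1] - pos[i, 1]
    two_r = 2.0 * config.radius * 1e6
    if config.interactions:
        for _ in range(10):
            moved = False
            for i in range(pos.shape[0] - 1):
                for j in range(i + 1, pos.shape[0]):
                    delta = pos[j] - pos[i]
                    d = float(np.linalg.norm(delta))
                    if d >= two_r:
                        continue
                    unit = delta / d if d > 1e-12 else np.array([1.0, 0.0, 0.0])
                    push = 0.5 * (two_r - d)
                    pos[i] -= push * unit
                    pos[j] += push * unit
                    moved = True
            if not moved:
                break
    return EnsembleState(positions=pos, time=state.time)


def detect_and_replace(state: EnsembleState, config: SimConfig,
                       rng: np.random.Generator):
    """Record membrane hits and redraw absorbed vesicles (python reference).

    Any center at or below the absorption plane produces one event at the
    current simulated time; the vesicle is replaced per the configured
    replacement rule and the ensemble size is unchanged.
    """
    lo, hi, absorb = config._geometry_um()
    two_r = 2.0 * config.radius * 1e6
    pos = state.positions.copy()
    events = []
    for i in range(pos.shape[0]):
        if pos[i, 1] <= absorb:
            events.append(state.time)
            for _ in range(10000):
                cand = lo + (hi - lo) * rng.random(3)
                cand[1] = absorb + (hi[1] - absorb) * rng.random()
                if not config.interactions:
                    break
                d = np.linalg.norm(np.delete(pos, i, axis=0) - cand, axis=1)
                if np.all(d >= two_r):
                    break
            else:
                raise RuntimeError("replacement packing failure")
            pos[i] = cand
    return EnsembleState(positions=pos, time=state.time), events


def _reflect_scalar(x, lo, hi):
    while x < lo or x > hi:
        if x < lo:
            x = 2.0 * lo - x
        else:
            x = 2.0 * hi - x
    return x


def run_simulation(config: SimConfig) -> SpikeSequence:
    """Run initialize → step loop until the stop criterion; return events.

    The returned sequence has duration equal to the simulated time and a
    label recording the convention triplet and seed for auditability.
    """
    ss = np.random.SeedSequence(config.seed)
    init_seed, kernel_seed = [int(s) for s in ss.generate_state(2) // 2]
    state = initialize_ensemble(config, seed=init_seed)
    args = _kernel_args(config)
    max_steps = int(np.ceil(config.max_time / config.dt))
    events = np.empty(config.stop_events)
    pos = np.ascontiguousarray(state.positions, dtype=np.float64)
    n_ev, t_end, unresolved, _ = _kernels.simulate_kernel(
        kernel_seed, pos, 0.0, args["lo"], args["hi"], args["absorb_y"],
        args["step_std"], args["k_drift"], args["y0"], args["dt"], args["two_r"],
        args["interactions"], args["membrane_reflecting"], args["replace_mode"],
        config.stop_events, max_steps, events)
    label = (f"langevin n={config.n} alpha={config.alpha:g} "
             f"noise={config.noise_convention} boundary={config.boundary} "
             f"replacement={config.replacement} dt={config.dt:g} seed={config.seed}")
    return SpikeSequence(times=events[:n_ev].copy(), duration=t_end, label=label)
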