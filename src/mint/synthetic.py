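"""Ground-truth spiking/behavior generators for testing.

Two generators are provided:

* a reach-style simulation in which firing rates are random rectified
  affine functions of z-scored kinematics (position/velocity/acceleration)
  and spikes are drawn from a Poisson process or a gamma-interval renewal
  process (shape 2, rate 2*lambda, matched long-run rate);
* a trajectory "world" with known per-condition rate trajectories, used to
  build a library with zero estimation error and to generate test trials
  (exact replays, time-dilated replays, fixed-alpha blends) carrying
  ground-truth (condition, index, alpha) labels per millisecond.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KinematicEncodingModel",
    "SpikingModel",
    "SyntheticWorld",
    "generate_kinematics",
    "simulate_rates",
    "sample_spikes",
    "make_world_and_trials",
]


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------


def _min_jerk(tn: np.ndarray):
    """Minimum-jerk profile and its exact derivatives on normalized time."""
    p = 10 * tn**3 - 15 * tn**4 + 6 * tn**5
    v = 30 * tn**2 - 60 * tn**3 + 30 * tn**4
    a = 60 * tn - 180 * tn**2 + 120 * tn**3
    return p, v, a


def generate_kinematics(
    n_conditions: int,
    n_trials: int,
    duration_ms: int,
    seed: int = 0,
    amplitude: float = 100.0,
    jitter: float = 0.05,
):
    """Minimum-jerk reaches to targets on a circle, with trial jitter.

    Returns a list of per-trial dicts with keys ``position``, ``velocity``,
    ``acceleration`` (each ``(2, T)``), ``condition`` and ``target``.
    Velocity and acceleration are the exact analytic derivatives of
    position (per ms), so numerical differentiation reproduces them up to
    discretization error.
    """
    if n_conditions < 1 or n_trials < 1 or duration_ms < 2:
        raise ValueError("need positive counts and duration >= 2 ms")
    rng = np.random.default_rng(seed)
    angles = 2 * np.pi * np.arange(n_conditions) / n_conditions
    targets = amplitude * np.stack([np.cos(angles), np.sin(angles)], axis=0)  # (2, C)
    t = np.arange(duration_ms, dtype=float)
    trials = []
    for c in range(n_conditions):
        for _ in range(n_trials):
            amp = 1.0 + jitter * rng.standard_normal()
            # movement occupies the middle of the trial; onset jittered
            onset = 0.15 * duration_ms * (1.0 + jitter * rng.standard_normal())
            move_dur = 0.6 * duration_ms * (1.0 + jitter * rng.standard_normal())
            tn = np.clip((t - onset) / move_dur, 0.0, 1.0)
            p, v, a = _min_jerk(tn)
            inside = (t >= onset) & (t <= onset + move_dur)
            v = np.where(inside, v / move_dur, 0.0)
            a = np.where(inside, a / move_dur**2, 0.0)
            tgt = amp * targets[:, c]
            trials.append(
                {
                    "position": tgt[:, None] * p[None, :],
                    "velocity": tgt[:, None] * v[None, :],
                    "acceleration": tgt[:, None] * a[None, :],
                    "condition": c,
                    "target": tgt,
                }
            )
    return trials


# ---------------------------------------------------------------------------
# Rates from kinematics
# ---------------------------------------------------------------------------


@dataclass
class KinematicEncodingModel:
    """Rates as a rectified random affine function of z-scored kinematics."""

    n_neurons: int = 100
    target_rate_mean: float = 20.0
    target_rate_sd: float = 10.0
    rate_multiplier: float = 1.0
    seed: int = 0
    weights: np.ndarray | None = None  # (N, 6)
    offsets: np.ndarray | None = None  # (N,)

    def __post_init__(self):
        rng = np.random.default_rng(self.seed)
        if self.weights is None:
            self.weights = rng.standard_normal((self.n_neurons, 6))
        if self.offsets is None:
            self.offsets = np.zeros(self.n_neurons)


def simulate_rates(kinematics: list, model: KinematicEncodingModel):
    """Simulate per-trial rates from kinematic trials.

    Kinematic channels (x/y position, velocity, acceleration) are z-scored
    across all trials and times; each neuron's rate is a rectified weighted
    sum plus offset, iteratively rescaled so the overall mean and SD of the
    rectified rates hit the model targets, then multiplied by
    ``rate_multiplier``.  Returns a list of ``(N, T)`` rate arrays (spikes/s).
    """
    feats = [
        np.concatenate([tr["position"], tr["velocity"], tr["acceleration"]], axis=0)
        for tr in kinematics
    ]
    allf = np.concatenate(feats, axis=1)  # (6, total T)
    mu = allf.mean(axis=1, keepdims=True)
    sd = allf.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance kinematic channel; cannot z-score")
    z = [(f - mu) / sd for f in feats]

    W, b = model.weights, model.offsets
    raw = [W @ zf + b[:, None] for zf in z]
    scale, shift = 1.0, model.target_rate_mean
    for _ in range(8):  # fixed-point rescaling; rectification shifts moments
        rates = [np.maximum(scale * r + shift, 0.0) for r in raw]
        flat = np.concatenate([r.ravel() for r in rates])
        emp_mean, emp_sd = flat.mean(), flat.std()
        if emp_sd > 0:
            scale *= model.target_rate_sd / emp_sd
        shift += model.target_rate_mean - emp_mean
    rates = [np.maximum(scale * r + shift, 0.0) * model.rate_multiplier for r in raw]
    return rates


# ---------------------------------------------------------------------------
# Spiking models
# ---------------------------------------------------------------------------


@dataclass
class SpikingModel:
    """Poisson or gamma-interval (shape 2, rate 2*lambda) spike generation."""

    kind: str = "poisson"
    gamma_shape: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("poisson", "gamma_interval"):
            raise ValueError(f"unknown spiking model {self.kind!r}")


def _poisson_times(rate_ms: np.ndarray, rng) -> np.ndarray:
    """Inhomogeneous Poisson event times (ms, float) by thinning."""
    T = rate_ms.size
    lam_max = float(rate_ms.max())
    if lam_max <= 0:
        return np.empty(0)
    n_cand = rng.poisson(lam_max * T)
    cand = np.sort(rng.uniform(0, T, n_cand))
    keep = rng.uniform(0, 1, n_cand) < rate_ms[np.floor(cand).astype(int)] / lam_max
    return cand[keep]


def _gamma_times(rate_ms: np.ndarray, rng, shape: float) -> np.ndarray:
    """Gamma-interval renewal times via time-rescaling.

    In rescaled time (unit intensity) inter-event intervals are
    Gamma(shape, rate=shape), giving mean interval 1 so the long-run rate
    matches the Poisson generator at equal lambda.
    """
    cum = np.concatenate([[0.0], np.cumsum(rate_ms)])  # rescaled time at ms edges
    total = cum[-1]
    if total <= 0:
        return np.empty(0)
    times_rescaled = []
    s = 0.0
    # draw in blocks for speed
    while s < total:
        block = rng.gamma(shape, 1.0 / shape, size=256)
        for isi in block:
            s += isi
            if s >= total:
                break
            times_rescaled.append(s)
    if not times_rescaled:
        return np.empty(0)
    ts = np.asarray(times_rescaled)
    idx = np.searchsorted(cum, ts, side="right") - 1
    frac = (ts - cum[idx]) / np.maximum(cum[idx + 1] - cum[idx], 1e-300)
    return idx + frac


def sample_spikes(rates: np.ndarray, model: SpikingModel, rng=None):
    """Sample spike trains from ``(N, T)`` rates (spikes/s, 1 kHz).

    Returns ``(counts, times)``: 1 kHz binned counts ``(N, T)`` and a list
    of per-neuron spike-time arrays (ms, float).
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("negative rates")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    N, T = rates.shape
    counts = np.zeros((N, T), dtype=np.int64)
    all_times = []
    for n in range(N):
        rate_ms = rates[n] / 1000.0
        if model.kind == "poisson":
            times = _poisson_times(rate_ms, rng)
        else:
            times = _gamma_times(rate_ms, rng, model.gamma_shape)
        all_times.append(times)
        if times.size:
            np.add.at(counts[n], np.floor(times).astype(int), 1)
    return counts, all_times


# ---------------------------------------------------------------------------
# Trajectory world
# ---------------------------------------------------------------------------


@dataclass
class SyntheticWorld:
    """A generative world with known rate/behavior trajectories.

    ``rates[c]`` are the true per-condition rate trajectories ``(N, Kc)``;
    ``behavior[c]`` the paired behavioral trajectories ``(M, Kc)``.  A
    library built from these noiseless rates (Type I averaging, no
    smoothing) equals them exactly.
    """

    rates: list
    behavior: list
    seed: int
    spiking: SpikingModel

    @property
    def n_neurons(self) -> int:
        return self.rates[0].shape[0]

    @property
    def n_conditions(self) -> int:
        return len(self.rates)

    def library(self, tau: int, delta_ms: int = 20):
        from .library import assemble_library

        return assemble_library(
            {c: r for c, r in enumerate(self.rates)},
            {c: z for c, z in enumerate(self.behavior)},
            tau=tau,
            delta_ms=delta_ms,
        )


def _softplus(x):
    return np.logaddexp(0.0, x)


def make_world(
    n_neurons: int = 100,
    n_conditions: int = 4,
    duration_ms: int = 800,
    latent_dim: int = 3,
    mean_rate: float = 20.0,
    seed: int = 0,
    spiking: SpikingModel | None = None,
) -> SyntheticWorld:
    """Build a world of smooth random latent trajectories.

    Latents are low-frequency random Fourier curves per condition; rates
    are a softplus readout scaled to the requested mean rate; behavior is a
    linear readout of the latents (2 variables).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(duration_ms) / duration_ms
    loadings = rng.standard_normal((n_neurons, latent_dim))
    b_map = rng.standard_normal((2, latent_dim))
    rates, behavior = [], []
    for c in range(n_conditions):
        lat = np.zeros((latent_dim, duration_ms))
        for f in range(1, 4):
            amp = rng.standard_normal((latent_dim, 1)) / f
            phase = rng.uniform(0, 2 * np.pi, (latent_dim, 1))
            lat += amp * np.sin(2 * np.pi * f * t[None, :] + phase)
        x = _softplus(loadings @ lat)
        rates.append(x)
        behavior.append(b_map @ lat)
    # scale all conditions jointly so the grand mean rate hits mean_rate
    grand = np.concatenate(rates, axis=1).mean()
    rates = [r * (mean_rate / grand) for r in rates]
    return SyntheticWorld(
        rates=rates,
        behavior=behavior,
        seed=seed,
        spiking=spiking or SpikingModel(seed=seed),
    )


def _dilate(trace: np.ndarray, factor: float) -> np.ndarray:
    """Time-dilate ``(D, K)`` by ``factor`` (>1 = slower) via linear interp."""
    K = trace.shape[1]
    new_len = int(round(K * factor))
    pos = np.linspace(0, K - 1, new_len)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, K - 1)
    w = pos - lo
    return trace[:, lo] * (1 - w) + trace[:, hi] * w


def make_world_and_trials(
    n_neurons: int = 100,
    n_conditions: int = 4,
    duration_ms: int = 800,
    n_replay: int = 2,
    n_dilated: int = 1,
    n_blend: int = 1,
    blend_alpha: float = 0.5,
    dilation: float = 1.15,
    mean_rate: float = 20.0,
    seed: int = 0,
    spiking_kind: str = "poisson",
):
    """Build a world plus spiking test trials with ground truth.

    Returns ``(world, trials)`` where each trial dict has ``counts``
    ``(N, T)``, ``kind`` in {replay, dilated, blend}, and per-ms ground
    truth: ``condition`` (or pair), ``index`` array, ``alpha``.
    """
    world = make_world(
        n_neurons, n_conditions, duration_ms, mean_rate=mean_rate, seed=seed,
        spiking=SpikingModel(kind=spiking_kind, seed=seed),
    )
    rng = np.random.default_rng(seed + 1)
    trials = []
    for c in range(world.n_conditions):
        for _ in range(n_replay):
            counts, _ = sample_spikes(world.rates[c], world.spiking, rng)
            trials.append(
                {
                    "kind": "replay",
                    "counts": counts,
                    "condition": c,
                    "index": np.arange(duration_ms),
                    "alpha": 0.0,
                    "behavior": world.behavior[c],
                }
            )
        for _ in range(n_dilated):
            f = dilation if rng.uniform() < 0.5 else 1.0 / dilation
            dil = _dilate(world.rates[c], f)
            counts, _ = sample_spikes(dil, world.spiking, rng)
            trials.append(
                {
                    "kind": "dilated",
                    "counts": counts,
                    "condition": c,
                    "index": np.linspace(0, duration_ms - 1, dil.shape[1]),
                    "alpha": 0.0,
                    "factor": f,
                }
            )
    pairs = [(c, (c + 1) % world.n_conditions) for c in range(world.n_conditions)]
    for c1, c2 in pairs[: max(n_blend * world.n_conditions, 0)]:
        for _ in range(n_blend):
            blend = (1 - blend_alpha) * world.rates[c1] + blend_alpha * world.rates[c2]
            counts, _ = sample_spikes(blend, world.spiking, rng)
            trials.append(
                {
                    "kind": "blend",
                    "counts": counts,
                    "condition": (c1, c2),
                    "index": np.arange(duration_ms),
                    "alpha": blend_alpha,
                }
            )
    return world, trials
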