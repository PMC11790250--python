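"""Learning paired libraries of idealized neural and behavioral trajectories.

The pipeline is: Gaussian-filter spikes to single-trial rates at 1 kHz,
extract event-aligned windows (optionally uniformly time-warped to the
per-condition median duration), average across trials (Type I arithmetic
mean, or Type II rank-1 trial-space reconstruction that suppresses outlier
trials), optionally smooth across neurons and/or conditions via PCA, and
assemble per-condition rate/behavior matrices into a
:class:`TrajectoryLibrary`.

Circular behavioral variables are stored in radians on ``[0, 2*pi)``;
degrees are accepted at I/O boundaries only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import convolve1d

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi

__all__ = [
    "TrialSet",
    "TrainingConfig",
    "TrajectoryLibrary",
    "SectionAdaptConfig",
    "gaussian_filter_spikes",
    "build_rates_from_trials",
    "average_trials",
    "average_behavior",
    "smooth_library",
    "assemble_library",
    "adapt_library_sections",
    "learn_library",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TrialSet:
    """Trial-structured training data.

    Parameters
    ----------
    spike_counts
        Per-trial ``(N, T)`` arrays of 1 kHz spike counts.
    behavior
        Per-trial ``(M, T)`` arrays of behavioral variables at 1 kHz.
    conditions
        Integer condition label per trial (0-based, contiguous).
    events
        Per-trial dict of named event times (ms, within ``[0, T)``).
    """

    spike_counts: list
    behavior: list
    conditions: np.ndarray
    events: list
    neuron_ids: list | None = None
    behavior_names: list | None = None

    def __post_init__(self):
        self.conditions = np.asarray(self.conditions, dtype=int)
        if not (
            len(self.spike_counts) == len(self.behavior) == len(self.conditions) == len(self.events)
        ):
            raise ValueError("spike_counts, behavior, conditions, events must have equal length")
        ns = {s.shape[0] for s in self.spike_counts}
        ms = {b.shape[0] for b in self.behavior}
        if len(ns) > 1:
            raise ValueError(f"all trials must share a neuron count, got {sorted(ns)}")
        if len(ms) > 1:
            raise ValueError(f"all trials must share a behavioral-variable count, got {sorted(ms)}")
        for i, (s, b) in enumerate(zip(self.spike_counts, self.behavior)):
            if s.shape[1] != b.shape[1]:
                raise ValueError(f"trial {i}: spike and behavior durations differ")
        if self.neuron_ids is None:
            self.neuron_ids = list(range(self.n_neurons))
        if self.behavior_names is None:
            self.behavior_names = [f"var{j}" for j in range(self.n_behavior)]

    @property
    def n_trials(self) -> int:
        return len(self.spike_counts)

    @property
    def n_neurons(self) -> int:
        return self.spike_counts[0].shape[0]

    @property
    def n_behavior(self) -> int:
        return self.behavior[0].shape[0]

    @classmethod
    def from_spike_times(cls, spike_times, durations, behavior, conditions, events, **kw):
        """Build from per-trial, per-neuron spike timestamp lists (ms)."""
        counts = []
        for trial, T in zip(spike_times, durations):
            mat = np.zeros((len(trial), int(T)), dtype=np.int64)
            for n, times in enumerate(trial):
                times = np.asarray(times, dtype=float)
                if times.size == 0:
                    continue
                if np.any((times < 0) | (times >= T)):
                    raise ValueError(f"spike times outside recording bounds [0, {T})")
                idx = np.floor(times).astype(int)
                np.add.at(mat[n], idx, 1)
            counts.append(mat)
        return cls(counts, behavior, conditions, events, **kw)


@dataclass
class TrainingConfig:
    """Hyperparameters for learning trajectories.

    ``window_start``/``window_end`` are offsets (ms) relative to
    ``start_event``/``end_event``; the extracted window is inclusive of both
    endpoints, so a fixed-event window of ``[-350, +750]`` yields 1101
    samples.  ``d_neural`` / ``d_condition`` are PCA smoothing
    dimensionalities, ``None`` meaning "full" (no reduction).
    """

    sigma_ms: float = 30.0
    start_event: str = "move"
    window_start: int = -500
    end_event: str = "move"
    window_end: int = 700
    averaging_mode: str = "type2"  # "type1" | "type2"
    d_neural: int | None = None
    d_condition: int | None = None
    soft_norm_constant: float = 5.0
    circular_flags: np.ndarray | None = None
    warp_mode: str = "none"  # "none" | "uniform"

    def __post_init__(self):
        if self.sigma_ms <= 0:
            raise ValueError("sigma_ms must be > 0")
        if self.averaging_mode not in ("type1", "type2"):
            raise ValueError(f"unknown averaging_mode {self.averaging_mode!r}")
        if self.warp_mode not in ("none", "uniform"):
            raise ValueError(f"unknown warp_mode {self.warp_mode!r}")


@dataclass
class TrajectoryLibrary:
    """Paired neural and behavioral trajectory libraries.

    ``rates[c]`` is ``(N, Kc)`` in spikes/s at 1 kHz; ``behavior[c]`` is
    ``(M, Kc)`` on the same time base.  State ``(c, k)`` is a valid decoding
    candidate iff ``k >= tau``.
    """

    rates: list
    behavior: list
    tau: int
    delta_ms: int
    circular_flags: np.ndarray
    neuron_ids: list
    behavior_names: list

    def __post_init__(self):
        self.circular_flags = np.asarray(self.circular_flags, dtype=bool)
        if len(self.rates) != len(self.behavior):
            raise ValueError("rates and behavior must have one matrix per condition")
        for c, (x, z) in enumerate(zip(self.rates, self.behavior)):
            if x.shape[1] != z.shape[1]:
                raise ValueError(f"condition {c + 1}: rate/behavior lengths differ")
            if not np.all(np.isfinite(x)) or np.any(x < 0):
                raise ValueError(f"condition {c + 1}: rates must be finite and non-negative")
        too_short = [c + 1 for c, x in enumerate(self.rates) if x.shape[1] < self.tau + 1]
        if too_short:
            raise ValueError(
                f"tau={self.tau} leaves no valid states in conditions {too_short} "
                f"(need Kc >= tau + 1)"
            )

    @property
    def n_conditions(self) -> int:
        return len(self.rates)

    @property
    def n_neurons(self) -> int:
        return self.rates[0].shape[0]

    @property
    def n_behavior(self) -> int:
        return self.behavior[0].shape[0]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([x.shape[1] for x in self.rates])

    def valid_state_mask(self, c: int) -> np.ndarray:
        m = np.zeros(self.rates[c].shape[1], dtype=bool)
        m[self.tau:] = True
        return m

    def state(self, c: int, k: int) -> np.ndarray:
        return self.rates[c][:, k]

    def behavior_state(self, c: int, k: int) -> np.ndarray:
        return self.behavior[c][:, k]

    def transition_back(self, c: int, k: int) -> int:
        """State-transition lookup: the predecessor index of state k."""
        if k <= 0:
            raise ValueError("state has no predecessor")
        return k - 1

    def subset_neurons(self, idx) -> "TrajectoryLibrary":
        idx = np.asarray(idx)
        return replace(
            self,
            rates=[x[idx] for x in self.rates],
            behavior=[z.copy() for z in self.behavior],
            neuron_ids=[self.neuron_ids[i] for i in idx],
        )

    def save(self, path):
        from .fileio import save_library

        save_library(self, path)

    @classmethod
    def load(cls, path) -> "TrajectoryLibrary":
        from .fileio import load_library

        return load_library(path)


@dataclass
class SectionAdaptConfig:
    """Configuration for adapting a session-wide library to session sections.

    ``epoch_weights`` is the diagonal of the per-sample observation weight
    matrix (length = total samples across conditions); defaults to all-ones
    when None.  The default weighting convention elsewhere in the package
    puts weight 4 on a designated epoch with ridge penalty 100.
    """

    ridge_lambda: float = 100.0
    epoch_weights: np.ndarray | None = None
    soft_norm_constant: float = 5.0

    def __post_init__(self):
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be >= 0")
        if self.epoch_weights is not None:
            self.epoch_weights = np.asarray(self.epoch_weights, dtype=float)
            if np.any(self.epoch_weights <= 0):
                raise ValueError("epoch_weights must be > 0")


# ---------------------------------------------------------------------------
# Filtering / extraction
# ---------------------------------------------------------------------------


def _gaussian_kernel(sigma_ms: float) -> np.ndarray:
    radius = int(np.ceil(4.0 * sigma_ms))
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma_ms) ** 2)
    return k / k.sum()


def gaussian_filter_spikes(counts: np.ndarray, sigma_ms: float) -> np.ndarray:
    """Filter 1 kHz spike counts ``(N, T)`` into rates in spikes/s.

    Uses a +/-4 sigma truncated Gaussian, renormalized at trial edges so a
    constant-rate spike train keeps its rate near the boundaries.
    """
    counts = np.asarray(counts, dtype=float)
    kernel = _gaussian_kernel(sigma_ms)
    smoothed = convolve1d(counts, kernel, axis=-1, mode="constant", cval=0.0)
    norm = convolve1d(np.ones(counts.shape[-1]), kernel, mode="constant", cval=0.0)
    return 1000.0 * smoothed / norm


def _resample_linear(trace: np.ndarray, new_len: int) -> np.ndarray:
    """Linearly resample ``(D, K)`` rows to ``(D, new_len)``."""
    K = trace.shape[1]
    if K < 2:
        raise ValueError("cannot warp a single-sample trial")
    pos = np.linspace(0.0, K - 1, new_len)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, K - 1)
    w = pos - lo
    return trace[:, lo] * (1.0 - w) + trace[:, hi] * w


def build_rates_from_trials(trials: TrialSet, cfg: TrainingConfig):
    """Filter, extract and align trials into per-condition tensors.

    Returns ``(X, Z)`` where ``X[c]`` is ``(N, Kc, Rc)`` single-trial rates
    (spikes/s) and ``Z[c]`` is ``(M, Kc, Rc)`` behavior, aligned to the
    configured event window.  With ``warp_mode='uniform'`` variable-duration
    windows are linearly resampled to the per-condition median duration.
    """
    per_cond_rates: dict = {}
    per_cond_behav: dict = {}
    for i in range(trials.n_trials):
        ev = trials.events[i]
        for name in (cfg.start_event, cfg.end_event):
            if name not in ev:
                raise ValueError(f"trial {i} is missing alignment event {name!r}")
        t0 = int(ev[cfg.start_event]) + int(cfg.window_start)
        t1 = int(ev[cfg.end_event]) + int(cfg.window_end)
        T = trials.spike_counts[i].shape[1]
        if t0 < 0 or t1 >= T:
            raise ValueError(
                f"trial {i}: extraction window [{t0}, {t1}] exceeds trial extent [0, {T - 1}]"
            )
        if t1 <= t0:
            raise ValueError(f"trial {i}: empty extraction window [{t0}, {t1}]")
        rates = gaussian_filter_spikes(trials.spike_counts[i], cfg.sigma_ms)[:, t0 : t1 + 1]
        behav = np.asarray(trials.behavior[i], dtype=float)[:, t0 : t1 + 1]
        if not np.all(np.isfinite(behav)):
            raise ValueError(f"trial {i}: non-finite behavior in extraction window")
        c = int(trials.conditions[i])
        per_cond_rates.setdefault(c, []).append(rates)
        per_cond_behav.setdefault(c, []).append(behav)

    X, Z = {}, {}
    for c in sorted(per_cond_rates):
        xs, zs = per_cond_rates[c], per_cond_behav[c]
        lengths = np.array([x.shape[1] for x in xs])
        if len(set(lengths.tolist())) > 1:
            if cfg.warp_mode != "uniform":
                raise ValueError(
                    f"condition {c + 1}: trials have unequal durations {sorted(set(lengths.tolist()))}; "
                    f"enable warp_mode='uniform' or use a fixed event window"
                )
            target = int(round(float(np.median(lengths))))
            xs = [_resample_linear(x, target) for x in xs]
            zs = [_resample_linear(z, target) for z in zs]
        X[c] = np.stack(xs, axis=2)
        Z[c] = np.stack(zs, axis=2)
    return X, Z


# ---------------------------------------------------------------------------
# Averaging
# ---------------------------------------------------------------------------


def soft_norm_params(rates: np.ndarray, constant: float):
    """Per-neuron (offset, scale) from rates ``(N, K)``.

    offset = mean rate; scale = 1 / (rate range + constant).
    """
    offset = rates.mean(axis=1)
    rng = rates.max(axis=1) - rates.min(axis=1)
    scale = 1.0 / (rng + constant)
    return offset, scale


def average_trials(
    tensor: np.ndarray,
    mode: str,
    cfg: TrainingConfig,
    norm_params=None,
) -> np.ndarray:
    """Average a rate tensor ``(N, K, R)`` across trials.

    Type I is the arithmetic mean.  Type II soft-normalizes and centers
    (offset/scale from the Type I average unless ``norm_params`` supplies
    ones computed across all conditions), reconstructs the trials from their
    first trial-space principal component, undoes the normalization, then
    averages.  The trial-space PC is taken as the top left singular vector
    of the ``(R, N*K)`` matrix without additional centering.
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.ndim != 3 or tensor.shape[2] < 1:
        raise ValueError("tensor must be (N, K, R) with at least one trial")
    if not np.all(np.isfinite(tensor)):
        raise ValueError("non-finite rates")
    if mode == "type1":
        return tensor.mean(axis=2)
    if mode != "type2":
        raise ValueError(f"unknown averaging mode {mode!r}")

    N, K, R = tensor.shape
    if norm_params is None:
        norm_params = soft_norm_params(tensor.mean(axis=2), cfg.soft_norm_constant)
    offset, scale = norm_params
    xn = (tensor - offset[:, None, None]) * scale[:, None, None]
    xin = xn.reshape(N * K, R).T  # (R, N*K)
    # rank-1 reconstruction across the trial dimension
    u, _, _ = np.linalg.svd(xin, full_matrices=False)
    w = u[:, :1]
    xout = w @ (w.T @ xin)
    xn = xout.T.reshape(N, K, R)
    x = xn / scale[:, None, None] + offset[:, None, None]
    return x.mean(axis=2)


def wrap_angle(theta):
    """Wrap angles (radians) to ``[0, 2*pi)``."""
    return np.mod(theta, TWO_PI)


def average_behavior(tensor: np.ndarray, circular_flags=None) -> np.ndarray:
    """Average a behavior tensor ``(M, K, R)`` across trials.

    Linear variables use the arithmetic mean.  Circular variables (radians)
    are unwrapped along time per trial, branch-aligned to the first trial,
    averaged, and re-wrapped to ``[0, 2*pi)``.
    """
    tensor = np.asarray(tensor, dtype=float)
    if not np.all(np.isfinite(tensor)):
        raise ValueError("non-finite behavior")
    M, K, R = tensor.shape
    if circular_flags is None:
        circular_flags = np.zeros(M, dtype=bool)
    circular_flags = np.asarray(circular_flags, dtype=bool)
    out = tensor.mean(axis=2)
    for m in np.where(circular_flags)[0]:
        unwrapped = np.unwrap(tensor[m], axis=0)  # (K, R) unwrap along time
        ref = unwrapped[0, 0]
        shift = TWO_PI * np.round((unwrapped[0, :] - ref) / TWO_PI)
        unwrapped = unwrapped - shift[None, :]
        out[m] = wrap_angle(unwrapped.mean(axis=1))
    return out


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------


def _top_pcs(mat: np.ndarray, d: int) -> np.ndarray:
    u, _, _ = np.linalg.svd(mat, full_matrices=False)
    return u[:, :d]


def smooth_library(avg_rates: dict, cfg: TrainingConfig) -> dict:
    """PCA-smooth trial-averaged rates across neurons and/or conditions.

    ``avg_rates`` maps condition -> ``(N, Kc)``.  Rates are soft-normalized
    and mean-centered, projected onto the top ``d_neural`` neural PCs and
    then (when all ``Kc`` agree) the top ``d_condition`` condition PCs, the
    normalization is undone, and the result is rectified at zero.
    Condition smoothing is skipped with a warning when trajectory lengths
    differ across conditions.
    """
    conds = sorted(avg_rates)
    mats = [np.asarray(avg_rates[c], dtype=float) for c in conds]
    N = mats[0].shape[0]
    lengths = [m.shape[1] for m in mats]
    concat = np.concatenate(mats, axis=1)  # (N, K)

    offset, scale = soft_norm_params(concat, cfg.soft_norm_constant)
    xn = (concat - offset[:, None]) * scale[:, None]

    if cfg.d_neural is not None:
        if cfg.d_neural > N:
            raise ValueError(f"d_neural={cfg.d_neural} exceeds neuron count {N}")
        w = _top_pcs(xn, cfg.d_neural)
        xn = w @ (w.T @ xn)

    if cfg.d_condition is not None:
        C = len(conds)
        if cfg.d_condition > C:
            raise ValueError(f"d_condition={cfg.d_condition} exceeds condition count {C}")
        if len(set(lengths)) > 1:
            warnings.warn(
                "condition smoothing skipped: trajectory lengths differ across conditions",
                stacklevel=2,
            )
        else:
            Kc = lengths[0]
            xin = xn.reshape(N, C, Kc).transpose(1, 0, 2).reshape(C, N * Kc)
            w = _top_pcs(xin, cfg.d_condition)
            xout = w @ (w.T @ xin)
            xn = xout.reshape(C, N, Kc).transpose(1, 0, 2).reshape(N, C * Kc)

    x = xn / scale[:, None] + offset[:, None]
    x = np.maximum(x, 0.0)

    out, pos = {}, 0
    for c, Kc in zip(conds, lengths):
        out[c] = x[:, pos : pos + Kc]
        pos += Kc
    return out


# ---------------------------------------------------------------------------
# Assembly and section adaptation
# ---------------------------------------------------------------------------


def assemble_library(
    rates: dict,
    behavior: dict,
    tau: int,
    delta_ms: int,
    circular_flags=None,
    neuron_ids=None,
    behavior_names=None,
) -> TrajectoryLibrary:
    """Pair per-condition rate and behavior matrices into a library."""
    if sorted(rates) != sorted(behavior):
        raise ValueError("rates and behavior must cover the same conditions")
    conds = sorted(rates)
    xs = [np.asarray(rates[c], dtype=float) for c in conds]
    zs = [np.asarray(behavior[c], dtype=float) for c in conds]
    M = zs[0].shape[0]
    if circular_flags is None:
        circular_flags = np.zeros(M, dtype=bool)
    if neuron_ids is None:
        neuron_ids = list(range(xs[0].shape[0]))
    if behavior_names is None:
        behavior_names = [f"var{j}" for j in range(M)]
    return TrajectoryLibrary(
        rates=xs,
        behavior=zs,
        tau=int(tau),
        delta_ms=int(delta_ms),
        circular_flags=circular_flags,
        neuron_ids=list(neuron_ids),
        behavior_names=list(behavior_names),
    )


def adapt_library_sections(
    library: TrajectoryLibrary,
    section_rate_estimates: list,
    cfg: SectionAdaptConfig,
) -> list:
    """Adapt a session-wide library to per-section rate estimates.

    Each element of ``section_rate_estimates`` maps condition -> ``(N, Kc)``
    raw per-section rates.  For each section ``d`` a ridge-regularized
    weighted least-squares transform ``(W Lam + I) X + b`` is fit so the
    transformed session-wide rates match the section rates, and a new
    library with the transformed (rectified) rates is returned per section.
    """
    conds = list(range(library.n_conditions))
    X = np.concatenate([library.rates[c] for c in conds], axis=1)  # (N, K)
    N, K = X.shape
    _, scale = soft_norm_params(X, cfg.soft_norm_constant)
    lam_diag = scale  # diagonal of the soft-normalizing matrix
    weights = cfg.epoch_weights if cfg.epoch_weights is not None else np.ones(K)
    if weights.shape != (K,):
        raise ValueError(f"epoch_weights must have length {K}")

    P = lam_diag[:, None] * X
    mu2 = P.mean(axis=1)
    P = P - mu2[:, None]
    PSPt = (P * weights[None, :]) @ P.T
    A = PSPt + cfg.ridge_lambda * np.eye(N)

    out = []
    for d, est in enumerate(section_rate_estimates):
        if sorted(est) != conds:
            raise ValueError(f"section {d}: condition set mismatch with library")
        Y = np.concatenate([np.asarray(est[c], dtype=float) for c in conds], axis=1)
        if Y.shape != X.shape:
            raise ValueError(f"section {d}: shape {Y.shape} does not match library {X.shape}")
        Qd = Y - X
        mu1 = Qd.mean(axis=1)
        Qd = Qd - mu1[:, None]
        QSPt = (Qd * weights[None, :]) @ P.T
        try:
            W = np.linalg.solve(A.T, QSPt.T).T
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular normal equations; use ridge_lambda > 0"
            ) from exc
        if cfg.ridge_lambda == 0 and not np.all(np.isfinite(W)):
            raise np.linalg.LinAlgError("singular normal equations; use ridge_lambda > 0")
        b = mu1 - W @ mu2
        adapted = X + W @ (lam_diag[:, None] * X) + b[:, None]
        adapted = np.maximum(adapted, 0.0)
        rates_d, pos = {}, 0
        for c in conds:
            Kc = library.rates[c].shape[1]
            rates_d[c] = adapted[:, pos : pos + Kc]
            pos += Kc
        out.append(
            assemble_library(
                rates_d,
                {c: library.behavior[c] for c in conds},
                library.tau,
                library.delta_ms,
                library.circular_flags,
                library.neuron_ids,
                library.behavior_names,
            )
        )
    return out


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------


def learn_library(
    trials: TrialSet,
    cfg: TrainingConfig,
    tau: int,
    delta_ms: int = 20,
) -> TrajectoryLibrary:
    """Full pipeline: filter/extract, average, smooth, assemble."""
    X, Z = build_rates_from_trials(trials, cfg)
    conds = sorted(X)
    type1 = {c: X[c].mean(axis=2) for c in conds}
    norm = soft_norm_params(np.concatenate([type1[c] for c in conds], axis=1), cfg.soft_norm_constant)
    avg = {c: average_trials(X[c], cfg.averaging_mode, cfg, norm_params=norm) for c in conds}
    smoothed = smooth_library(avg, cfg)
    flags = cfg.circular_flags
    if flags is None:
        flags = np.zeros(trials.n_behavior, dtype=bool)
    behav = {c: average_behavior(Z[c], flags) for c in conds}
    return assemble_library(
        smoothed,
        behav,
        tau=tau,
        delta_ms=delta_ms,
        circular_flags=flags,
        neuron_ids=trials.neuron_ids,
        behavior_names=trials.behavior_names,
    )
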