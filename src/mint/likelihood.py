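"""Poisson spike-count log-likelihoods over the trajectory library.

A :class:`LikelihoodTable` holds clipped log Poisson probabilities on a
discretized rate grid so that scoring a library state reduces to table
gathers.  :class:`RateIndexLibrary` maps every (neuron, sample) of the
library to its nearest grid index via bin-averaged rates, and
:class:`RecursiveEngine` maintains the per-bin recursive log-likelihood
update over the downsampled state grid.

Grid/state alignment: a state at sample ``k`` owns the spike-count bin of
the ``delta`` samples ending at ``k``.  The downsampled grid consists of
states ``k = delta*(k' + 1) - 1``; grid state ``k'`` has full history iff
``k' >= tau_prime`` (i.e. ``k >= delta*(tau_prime + 1) - 1``).
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import poisson

logger = logging.getLogger(__name__)

DEFAULT_CLIP_FLOOR = float(np.log(1e-6))
DEFAULT_RATE_FLOOR = 1.0  # spikes/s

__all__ = [
    "LikelihoodTable",
    "RateIndexLibrary",
    "BinnedSpikeBuffer",
    "build_lookup_table",
    "discretize_library_rates",
    "bin_spikes",
    "log_likelihood_direct",
    "RecursiveEngine",
]


@dataclass
class LikelihoodTable:
    """Precomputed clipped log Poisson probabilities.

    ``entries[s, v]`` is ``max(clip_floor, log Pois(s; rate_grid[v] * delta_ms/1000))``
    for spike count ``s`` in a ``delta_ms`` bin.
    """

    rate_grid: np.ndarray  # (V+1,) spikes/s
    delta_ms: int
    entries: np.ndarray  # (S+1, V+1)
    clip_floor: float
    rate_floor: float

    @property
    def max_count(self) -> int:
        return self.entries.shape[0] - 1

    @property
    def n_rates(self) -> int:
        return self.rate_grid.size

    @property
    def grid_step(self) -> float:
        return float(self.rate_grid[1] - self.rate_grid[0])

    def lookup_index(self, rates: np.ndarray) -> np.ndarray:
        """Nearest grid index for rates (spikes/s), after flooring.

        Rates below ``rate_floor`` are raised to the floor before index
        assignment; rates above the grid maximum are an error.
        """
        rates = np.asarray(rates, dtype=float)
        lam_max = float(self.rate_grid[-1])
        if np.any(rates > lam_max):
            n = int(np.argmax(np.max(rates, axis=tuple(range(1, rates.ndim))) > lam_max)) if rates.ndim > 1 else -1
            raise ValueError(
                f"rate {rates.max():.3f} spikes/s exceeds table maximum {lam_max}; "
                f"build a larger table" + (f" (neuron {n})" if n >= 0 else "")
            )
        floored = np.maximum(rates, self.rate_floor)
        idx = np.round((floored - self.rate_grid[0]) / self.grid_step)
        return np.clip(idx, 0, self.n_rates - 1).astype(np.int64)


def build_lookup_table(
    lambda_min: float = 0.0,
    lambda_max: float = 200.0,
    grid_step: float = 0.1,
    max_count: int = 20,
    delta_ms: int = 20,
    clip_floor: float = DEFAULT_CLIP_FLOOR,
    rate_floor: float = DEFAULT_RATE_FLOOR,
) -> LikelihoodTable:
    """Build the clipped Poisson log-likelihood lookup table.

    The rate axis runs from ``lambda_min`` to ``lambda_max`` inclusive in
    ``grid_step`` increments; the count axis runs 0..``max_count``.
    """
    if lambda_min < 0 or lambda_max <= lambda_min:
        raise ValueError("require 0 <= lambda_min < lambda_max")
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    if max_count < 1:
        raise ValueError("max_count must be >= 1")
    V = int(round((lambda_max - lambda_min) / grid_step))
    grid = lambda_min + grid_step * np.arange(V + 1)
    mu = grid * (delta_ms / 1000.0)  # expected counts per bin
    s = np.arange(max_count + 1)
    with np.errstate(divide="ignore"):
        entries = poisson.logpmf(s[:, None], mu[None, :])
    entries = np.maximum(entries, clip_floor)
    return LikelihoodTable(
        rate_grid=grid,
        delta_ms=int(delta_ms),
        entries=entries,
        clip_floor=float(clip_floor),
        rate_floor=float(rate_floor),
    )


# ---------------------------------------------------------------------------
# Library discretization
# ---------------------------------------------------------------------------


@dataclass
class RateIndexLibrary:
    """Library rates bin-averaged and mapped to lookup-table indices.

    ``binned_rates[c][n, k]`` is the mean rate (spikes/s) over the ``delta``
    samples ending at ``k`` (NaN where ``k < delta - 1``);
    ``index_full[c]`` holds the nearest grid index (-1 where undefined);
    ``index_grid[c][n, k']`` restricts to the downsampled grid states.
    """

    table: LikelihoodTable
    binned_rates: list
    index_full: list
    index_grid: list
    grid_samples: list  # grid_samples[c][k'] = library sample index of grid state k'
    tau: int

    @property
    def n_conditions(self) -> int:
        return len(self.index_full)

    @property
    def n_neurons(self) -> int:
        return self.index_full[0].shape[0]

    def grid_lengths(self) -> np.ndarray:
        return np.array([g.size for g in self.grid_samples])

    def min_valid_grid_index(self) -> int:
        """Smallest k' whose state has a full ``tau``-sample history."""
        delta = self.table.delta_ms
        return int(np.ceil((self.tau + 1) / delta)) - 1

    def history(self, c: int, k: int, tau_prime: int) -> np.ndarray:
        """Bin-averaged rate history ``(tau_prime+1, N)`` ending at sample k.

        Row ``i`` is the bin ending at ``k - delta*(tau_prime - i)`` (oldest
        first).  Bins extending before the trajectory start are NaN.
        """
        delta = self.table.delta_ms
        ks = k - delta * np.arange(tau_prime, -1, -1)
        out = np.full((tau_prime + 1, self.n_neurons), np.nan)
        ok = ks >= delta - 1
        if ok.any():
            out[ok] = self.binned_rates[c][:, ks[ok]].T
        return out


def discretize_library_rates(library, table: LikelihoodTable) -> RateIndexLibrary:
    """Bin-average library rates and map them to lookup-table indices."""
    delta = table.delta_ms
    binned, idx_full, idx_grid, grid_samples = [], [], [], []
    for c, rates in enumerate(library.rates):
        N, Kc = rates.shape
        cs = np.concatenate([np.zeros((N, 1)), np.cumsum(rates, axis=1)], axis=1)
        lam = np.full((N, Kc), np.nan)
        js = np.arange(delta - 1, Kc)
        lam[:, js] = (cs[:, js + 1] - cs[:, js + 1 - delta]) / delta
        vi = np.full((N, Kc), -1, dtype=np.int64)
        if js.size:
            vi[:, js] = table.lookup_index(lam[:, js])
        ks = np.arange(delta - 1, Kc, delta)  # grid states k = delta*(k'+1) - 1
        binned.append(lam)
        idx_full.append(vi)
        idx_grid.append(vi[:, ks])
        grid_samples.append(ks)
    return RateIndexLibrary(
        table=table,
        binned_rates=binned,
        index_full=idx_full,
        index_grid=idx_grid,
        grid_samples=grid_samples,
        tau=library.tau,
    )


# ---------------------------------------------------------------------------
# Spike binning
# ---------------------------------------------------------------------------


def bin_spikes(stream: np.ndarray, delta_ms: int):
    """Sum a 1 kHz count stream ``(N, T)`` into ``delta_ms`` bins.

    Returns ``(binned, remainder)`` where ``binned`` is ``(N, T // delta)``
    (half-open windows ``[i*delta, (i+1)*delta)``) and ``remainder`` the
    number of trailing samples not forming a complete bin.
    """
    stream = np.asarray(stream)
    if np.any(stream < 0):
        raise ValueError("negative spike counts")
    N, T = stream.shape
    nbins = T // delta_ms
    binned = stream[:, : nbins * delta_ms].reshape(N, nbins, delta_ms).sum(axis=2)
    return binned, T - nbins * delta_ms


class BinnedSpikeBuffer:
    """Ring buffer of the ``tau_prime + 1`` most recent completed bins.

    Counts above ``max_count`` are clamped with a warning (the table has no
    entries beyond it).  ``samples_since_bin`` is the delta-counter: 0
    immediately after a bin completes.
    """

    def __init__(self, n_neurons: int, delta_ms: int, tau_prime: int, max_count: int):
        self.n_neurons = n_neurons
        self.delta_ms = int(delta_ms)
        self.tau_prime = int(tau_prime)
        self.max_count = int(max_count)
        self.reset()

    def reset(self):
        self._bins = deque(maxlen=self.tau_prime + 1)
        self._accum = np.zeros(self.n_neurons, dtype=np.int64)
        self._pos = 0
        self.bins_completed = 0

    @property
    def samples_since_bin(self) -> int:
        return self._pos

    def push_sample(self, counts: np.ndarray) -> bool:
        """Ingest one 1 ms count vector; return True if a bin completed."""
        counts = np.asarray(counts)
        if np.any(counts < 0):
            raise ValueError("negative spike counts")
        self._accum += counts
        self._pos += 1
        if self._pos == self.delta_ms:
            self.push_bin(self._accum)
            self._accum = np.zeros(self.n_neurons, dtype=np.int64)
            self._pos = 0
            return True
        return False

    def push_bin(self, counts: np.ndarray):
        counts = np.asarray(counts, dtype=np.int64)
        if np.any(counts < 0):
            raise ValueError("negative spike counts")
        if np.any(counts > self.max_count):
            logger.warning(
                "spike count %d exceeds table maximum %d; clamping",
                int(counts.max()),
                self.max_count,
            )
            counts = np.minimum(counts, self.max_count)
        self._bins.append(counts)
        self.bins_completed += 1
        self._pos = 0

    def counts(self) -> np.ndarray:
        """Stacked ``(n_held, N)`` bins, oldest first."""
        return np.array(self._bins, dtype=np.int64).reshape(len(self._bins), self.n_neurons)

    def full(self) -> bool:
        return len(self._bins) == self.tau_prime + 1


# ---------------------------------------------------------------------------
# Direct and recursive likelihood
# ---------------------------------------------------------------------------


def log_likelihood_direct(
    buffer_counts: np.ndarray,
    rate_index: RateIndexLibrary,
    c: int,
    k: int,
    active: np.ndarray | None = None,
    count_lookups: bool = False,
):
    """Direct log-likelihood of state ``(c, k)`` given recent binned counts.

    ``buffer_counts`` is ``(n_bins, N)``, oldest bin first, the newest bin
    aligned with the bin ending at sample ``k``.  Bins that would extend
    before the trajectory start (or before the stream start) contribute 0.
    With ``count_lookups=True`` returns ``(q, n_lookups)``.
    """
    table = rate_index.table
    delta = table.delta_ms
    counts = np.asarray(buffer_counts, dtype=np.int64)
    n_bins = counts.shape[0]
    vi = rate_index.index_full[c]
    if active is None:
        active = np.ones(rate_index.n_neurons, dtype=bool)
    q = 0.0
    n_lookups = 0
    for i in range(n_bins):  # i = 0 oldest
        kj = k - delta * (n_bins - 1 - i)
        if kj < delta - 1:
            continue
        v = vi[active, kj]
        s = np.minimum(counts[i, active], table.max_count)
        q += float(table.entries[s, v].sum())
        n_lookups += int(active.sum())
    if count_lookups:
        return q, n_lookups
    return q


class RecursiveEngine:
    """Recursive per-bin update of log-likelihoods over the state grid.

    For each condition, maintains ``q[k']`` = log-likelihood that the newest
    completed bin is the bin owned by grid state ``k'``, summed over the
    last ``tau_prime + 1`` bins.  Each new bin triggers
    ``q_new[k'] = q_old[k'-1] + r_new[k'] - r_oldest[k' - tau_prime - 1]``
    with zero boundary conditions, which is algebraically identical to the
    direct sum.
    """

    def __init__(self, rate_index: RateIndexLibrary, tau_prime: int, active: np.ndarray | None = None):
        self.rate_index = rate_index
        self.table = rate_index.table
        self.tau_prime = int(tau_prime)
        if active is None:
            active = np.ones(rate_index.n_neurons, dtype=bool)
        self.active = np.asarray(active, dtype=bool)
        self.reset()

    def reset(self):
        self.q = [np.zeros(g.size) for g in self.rate_index.grid_samples]
        self._r_hist = [deque(maxlen=self.tau_prime + 1) for _ in self.q]
        self.bins_seen = 0

    def set_active(self, active: np.ndarray):
        self.active = np.asarray(active, dtype=bool)

    def _r_vector(self, c: int, counts: np.ndarray) -> np.ndarray:
        """Per-grid-state single-bin log-likelihood for one count vector."""
        vg = self.rate_index.index_grid[c][self.active]
        s = np.minimum(counts[self.active], self.table.max_count)
        return self.table.entries[s[:, None], vg].sum(axis=0)

    def update(self, bin_counts: np.ndarray):
        """Fold one newly completed bin (length-N counts) into the recursion."""
        bin_counts = np.asarray(bin_counts, dtype=np.int64)
        tp1 = self.tau_prime + 1
        for c in range(self.rate_index.n_conditions):
            r_new = self._r_vector(c, bin_counts)
            hist = self._r_hist[c]
            r_old = hist[0] if len(hist) == tp1 else None
            q_old = self.q[c]
            q_new = np.empty_like(q_old)
            q_new[0] = 0.0
            q_new[1:] = q_old[:-1]
            q_new += r_new
            if r_old is not None:
                q_new[tp1:] -= r_old[: q_new.size - tp1]
            self.q[c] = q_new
            hist.append(r_new)
        self.bins_seen += 1

    def rebuild(self, bins: np.ndarray):
        """Recompute the recursion from scratch off ``(n_bins, N)`` counts."""
        seen = self.bins_seen
        self.reset()
        for row in np.asarray(bins, dtype=np.int64):
            self.update(row)
        self.bins_seen = seen

    def most_likely_state(self, min_grid_index: int | None = None):
        """Argmax of q over grid states with full history.

        Returns ``(c, k_prime, q)``; ties break to the lowest (c, k').
        """
        if min_grid_index is None:
            min_grid_index = max(self.tau_prime, self.rate_index.min_valid_grid_index())
        best = None
        for c, q in enumerate(self.q):
            if q.size <= min_grid_index:
                continue
            sub = q[min_grid_index:]
            j = int(np.argmax(sub))
            val = float(sub[j])
            if best is None or val > best[2]:
                best = (c, min_grid_index + j, val)
        if best is None:
            raise ValueError("no valid grid states to select from")
        return best
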