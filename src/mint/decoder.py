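"""Online/offline decoding loop.

Spikes are ingested one millisecond at a time.  Every ``delta_ms`` samples a
bin completes: the recursive engine refreshes the grid log-likelihoods, the
most likely grid state is selected, and interpolation refines it.  Between
bin completions the estimate advances deterministically along its
trajectory (interpolation coefficients frozen, indices incremented).

Estimates are emitted for every input sample; those produced before a full
spiking-history window has accumulated are flagged invalid ("warm-up")
rather than omitted, keeping output aligned with input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .interpolate import CandidatePolicy, InterpolationResult, refine_estimate
from .likelihood import (
    DEFAULT_CLIP_FLOOR,
    DEFAULT_RATE_FLOOR,
    BinnedSpikeBuffer,
    RecursiveEngine,
    build_lookup_table,
    discretize_library_rates,
)

logger = logging.getLogger(__name__)

__all__ = ["DecoderConfig", "Decoder", "Estimate", "DecodeResult"]


@dataclass
class DecoderConfig:
    """Decoding parameters.

    ``window_ms`` is the total spiking history ``(tau_prime + 1) * delta_ms``.
    ``interp`` selects the refinement mode (off/index/condition/library);
    ``lag_ms`` shifts emission of estimates (positive = output at time t
    describes time t - lag).
    """

    delta_ms: int = 20
    window_ms: int = 300
    causal: bool = True
    interp: str = "condition"
    n_candidates: int = 2
    min_separation_ms: int = 1000
    exclusion_rule: str | None = None
    library_tags: np.ndarray | None = None
    rate_floor: float = DEFAULT_RATE_FLOOR
    clip_floor: float = DEFAULT_CLIP_FLOOR
    grid_step: float = 0.1
    max_count: int = 20
    lag_ms: int = 0
    active_neuron_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.window_ms <= 0 or self.window_ms % self.delta_ms != 0:
            raise ValueError("window_ms must be a positive multiple of delta_ms")

    @property
    def tau_prime(self) -> int:
        return self.window_ms // self.delta_ms - 1

    @property
    def tau(self) -> int:
        return self.window_ms - 1

    def policy(self) -> CandidatePolicy:
        rule = self.exclusion_rule
        if rule is None:
            rule = "different_library" if self.interp == "library" else "different_condition"
        return CandidatePolicy(
            mode=self.interp,
            n_candidates=self.n_candidates,
            min_separation_ms=self.min_separation_ms,
            exclusion_rule=rule,
            library_tags=self.library_tags,
        )


@dataclass
class Estimate:
    """Per-millisecond decoded state."""

    t: int
    rates: np.ndarray
    behavior: np.ndarray
    log_likelihood: float
    provenance: tuple  # (c1, k1, c2, k2, alpha)
    valid: bool
    interpolation: InterpolationResult | None = None


@dataclass
class DecodeResult:
    """Column-stacked estimates for a decoded stream."""

    time: np.ndarray
    rates: np.ndarray  # (N, T)
    behavior: np.ndarray  # (M, T)
    log_likelihood: np.ndarray
    provenance: np.ndarray  # (5, T)
    valid: np.ndarray
    estimates: list = field(default_factory=list, repr=False)

    @classmethod
    def from_estimates(cls, ests, n_neurons, n_behavior):
        T = len(ests)
        time = np.array([e.t for e in ests], dtype=int)
        rates = np.full((n_neurons, T), np.nan)
        behavior = np.full((n_behavior, T), np.nan)
        ll = np.full(T, np.nan)
        prov = np.full((5, T), np.nan)
        valid = np.zeros(T, dtype=bool)
        for j, e in enumerate(ests):
            valid[j] = e.valid
            if e.valid:
                rates[:, j] = e.rates
                behavior[:, j] = e.behavior
                ll[j] = e.log_likelihood
                prov[:, j] = e.provenance
        return cls(time, rates, behavior, ll, prov, valid, list(ests))


class Decoder:
    """Maximum-likelihood decoder over a trajectory library."""

    def __init__(self, library, config: DecoderConfig | None = None):
        self.library = library
        self.config = config or DecoderConfig(delta_ms=library.delta_ms)
        if self.config.delta_ms != library.delta_ms:
            logger.info(
                "decoder bin width %d ms overrides library delta %d ms",
                self.config.delta_ms,
                library.delta_ms,
            )
        lam_max = max(max(float(x.max()) for x in library.rates), self.config.rate_floor)
        self.table = build_lookup_table(
            lambda_min=0.0,
            lambda_max=float(np.ceil(lam_max * 1.2 / self.config.grid_step) * self.config.grid_step),
            grid_step=self.config.grid_step,
            max_count=self.config.max_count,
            delta_ms=self.config.delta_ms,
            clip_floor=self.config.clip_floor,
            rate_floor=self.config.rate_floor,
        )
        self.rate_index = discretize_library_rates(library, self.table)
        mask = self.config.active_neuron_mask
        if mask is None:
            mask = np.ones(library.n_neurons, dtype=bool)
        self._active = np.asarray(mask, dtype=bool)
        if self._active.shape != (library.n_neurons,):
            raise ValueError("active_neuron_mask length must equal library neuron count")
        if not self._active.any():
            raise ValueError("active_neuron_mask must keep at least one neuron")
        self._policy = self.config.policy()
        self.reset()

    # -- state management ---------------------------------------------------

    def reset(self):
        cfg = self.config
        self.buffer = BinnedSpikeBuffer(
            self.library.n_neurons, cfg.delta_ms, cfg.tau_prime, cfg.max_count
        )
        self.engine = RecursiveEngine(self.rate_index, cfg.tau_prime, self._active)
        self._t = -1
        self._current: InterpolationResult | None = None
        self._mask_dirty = False

    def set_active_neurons(self, mask):
        """Mask neurons out of all likelihood computations (no retraining).

        Takes effect at the next completed bin; the recursion is rebuilt
        from the buffered bins so masking is exactly equivalent to decoding
        with the masked neurons removed from library and stream.
        """
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.library.n_neurons,):
            raise ValueError("mask length must equal library neuron count")
        if not mask.any():
            raise ValueError("mask must keep at least one neuron")
        self._active = mask
        self._mask_dirty = True

    @property
    def active_neurons(self) -> np.ndarray:
        return self._active.copy()

    # -- decoding -----------------------------------------------------------

    def step(self, counts_ms: np.ndarray) -> Estimate:
        """Ingest one 1 ms count vector and return the estimate at that time."""
        counts_ms = np.asarray(counts_ms)
        if counts_ms.shape != (self.library.n_neurons,):
            raise ValueError(
                f"expected {self.library.n_neurons} neuron counts, got {counts_ms.shape}"
            )
        self._t += 1
        completed = self.buffer.push_sample(counts_ms)
        if completed:
            self._on_bin_complete()
        elif self._current is not None:
            self._current = self._current.advance(1, self.library.lengths)
        return self._emit()

    def step_bin(self, bin_counts: np.ndarray) -> Estimate:
        """Ingest one pre-binned ``delta_ms`` count vector."""
        self._t += self.config.delta_ms
        self.buffer.push_bin(bin_counts)
        self._on_bin_complete()
        return self._emit()

    def _on_bin_complete(self):
        if self._mask_dirty:
            self.engine.set_active(self._active)
            self.engine.rebuild(self.buffer.counts()[:-1])
            self._mask_dirty = False
        self.engine.update(self.buffer.counts()[-1])
        if self.buffer.full():
            best = self.engine.most_likely_state()
            self._current = refine_estimate(
                best,
                self.engine.q,
                self.rate_index,
                self.buffer.counts(),
                self._policy,
                self.library,
                self._active,
            )

    def _emit(self) -> Estimate:
        if self._current is None:
            n, m = self.library.n_neurons, self.library.n_behavior
            return Estimate(
                self._t,
                np.full(n, np.nan),
                np.full(m, np.nan),
                np.nan,
                (-1, -1, -1, -1, np.nan),
                valid=False,
            )
        cur = self._current
        return Estimate(
            self._t,
            cur.rates(self.library),
            cur.behavior(self.library),
            cur.objective,
            cur.provenance,
            valid=True,
            interpolation=cur,
        )

    def decode(self, stream: np.ndarray, reset: bool = True) -> DecodeResult:
        """Decode a 1 kHz count stream ``(N, T)`` causally.

        Batch decoding is sample-by-sample streaming under the hood, so the
        two are exactly equivalent.
        """
        stream = np.asarray(stream)
        if stream.ndim != 2 or stream.shape[0] != self.library.n_neurons:
            raise ValueError(
                f"stream must be (N={self.library.n_neurons}, T), got {stream.shape}"
            )
        if reset:
            self.reset()
        ests = [self.step(stream[:, t]) for t in range(stream.shape[1])]
        if self.config.lag_ms:
            ests = _apply_lag(ests, self.config.lag_ms, self.library)
        return DecodeResult.from_estimates(ests, self.library.n_neurons, self.library.n_behavior)

    def decode_acausal(self, stream: np.ndarray) -> DecodeResult:
        """Decode a finite segment with (where possible) centered windows.

        The acausal estimate at time t is obtained from the causal estimate
        at ``u = t + window/2`` (whose spiking window is centered on t) by
        rewinding the selected state ``window/2`` samples along its
        trajectories with interpolation parameters frozen.  Near the segment
        boundaries the earliest feasible estimate is propagated backward and
        the latest forward in the same way.
        """
        causal = self.decode(stream)
        T = causal.time.size
        shift = self.config.window_ms // 2
        lengths = self.library.lengths
        valid_idx = np.where(causal.valid)[0]
        if valid_idx.size == 0:
            return causal
        first, last = int(valid_idx[0]), int(valid_idx[-1])
        ests = []
        for t in range(T):
            u = min(max(t + shift, first), last)
            cur = causal.estimates[u].interpolation.advance(t - u, lengths)
            ests.append(
                Estimate(
                    t,
                    cur.rates(self.library),
                    cur.behavior(self.library),
                    causal.estimates[u].log_likelihood,
                    cur.provenance,
                    valid=True,
                    interpolation=cur,
                )
            )
        return DecodeResult.from_estimates(ests, self.library.n_neurons, self.library.n_behavior)

    # -- held-out prediction -------------------------------------------------

    def predict_heldout_rates(self, result, heldout_library, floor: float = 0.1) -> np.ndarray:
        """Map decoded provenance onto a held-out neuron partition.

        The held-out rate estimate is the same convex combination of
        held-out library states as the decoded estimate's combination of
        held-in states, floored at ``floor`` spikes/s.
        """
        if list(heldout_library.lengths) != list(self.library.lengths):
            raise ValueError("held-out library must share condition lengths with the held-in library")
        ests = result.estimates if isinstance(result, DecodeResult) else result
        out = np.full((heldout_library.n_neurons, len(ests)), np.nan)
        for j, e in enumerate(ests):
            if not e.valid or e.interpolation is None:
                continue
            acc = np.zeros(heldout_library.n_neurons)
            for c, k, w in e.interpolation.weights():
                acc += w * heldout_library.rates[c][:, k]
            out[:, j] = np.maximum(acc, floor)
        return out


def _apply_lag(ests, lag_ms, library):
    """Shift emission by lag_ms (positive: estimate for t-lag emitted at t)."""
    T = len(ests)
    out = []
    for t in range(T):
        src = t - lag_ms
        if 0 <= src < T:
            out.append(replace(ests[src], t=t))
        else:
            n, m = library.n_neurons, library.n_behavior
            out.append(
                Estimate(t, np.full(n, np.nan), np.full(m, np.nan), np.nan,
                         (-1, -1, -1, -1, np.nan), valid=False)
            )
    return out
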