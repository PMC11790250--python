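"""Refining candidate states by interpolating between library states.

The spike log-likelihood of a convex combination of two states' rate
histories is concave in the mixing coefficient ``alpha``, so Newton's
method finds the maximizer in a handful of iterations.  Refinement
proceeds in stages: a candidate grid state is first interpolated with its
better adjacent grid state along the same trajectory (index refinement),
then optionally with a second, independently index-refined candidate from
a different trajectory (condition refinement) or a different library
section (library refinement).

The final estimate is a nested convex combination of up to four library
states, represented exactly by :class:`InterpolationResult` so it can be
re-blended after deterministic advance and applied to held-out neuron
partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammaln

from .library import TWO_PI, wrap_angle

logger = logging.getLogger(__name__)

__all__ = [
    "CandidatePolicy",
    "IndexBlend",
    "InterpolationResult",
    "interpolation_objective",
    "optimize_alpha",
    "refine_estimate",
    "circular_blend",
]


@dataclass
class CandidatePolicy:
    """How candidate states are chosen for interpolation.

    ``mode``: one of ``off``, ``index``, ``condition``, ``library``.
    ``n_candidates`` > 2 evaluates all unordered pairs among the top
    candidates (admissible under ``exclusion_rule``) and keeps the best.
    ``exclusion_rule``: ``different_condition`` requires the second
    candidate to lie on another trajectory; ``min_separation`` also admits
    same-trajectory states at least ``min_separation_ms`` away.
    """

    mode: str = "condition"
    n_candidates: int = 2
    min_separation_ms: int = 1000
    exclusion_rule: str = "different_condition"
    library_tags: np.ndarray | None = None

    def __post_init__(self):
        if self.mode not in ("off", "index", "condition", "library"):
            raise ValueError(f"unknown interpolation mode {self.mode!r}")
        if self.mode in ("condition", "library") and self.n_candidates < 2:
            raise ValueError("n_candidates must be >= 2 when interpolation is enabled")
        if self.min_separation_ms < 0:
            raise ValueError("min_separation_ms must be >= 0")
        if self.exclusion_rule not in ("different_condition", "min_separation", "different_library"):
            raise ValueError(f"unknown exclusion_rule {self.exclusion_rule!r}")
        if self.mode == "library" and self.library_tags is None:
            raise ValueError("library mode requires library_tags (one tag per condition)")


@dataclass
class IndexBlend:
    """A within-trajectory blend of state ``k_a`` and neighbor ``k_b``."""

    c: int
    k_a: int
    k_b: int
    alpha: float

    def advance(self, steps: int, length: int) -> "IndexBlend":
        ka = self.k_a + steps
        kb = self.k_b + steps
        if max(ka, kb) > length - 1:
            over = max(ka, kb) - (length - 1)
            ka, kb = ka - over, kb - over
        if min(ka, kb) < 0:
            under = -min(ka, kb)
            ka, kb = ka + under, kb + under
        return replace(self, k_a=ka, k_b=kb)

    def rates(self, library) -> np.ndarray:
        x = library.rates[self.c]
        return (1.0 - self.alpha) * x[:, self.k_a] + self.alpha * x[:, self.k_b]

    def behavior(self, library) -> np.ndarray:
        z = library.behavior[self.c]
        return blend_behavior(
            z[:, self.k_a], z[:, self.k_b], self.alpha, library.circular_flags
        )

    def weights(self):
        return [(self.c, self.k_a, 1.0 - self.alpha), (self.c, self.k_b, self.alpha)]


@dataclass
class InterpolationResult:
    """Final (possibly nested) interpolated estimate.

    The estimate is ``(1 - alpha) * anchor_a + alpha * anchor_b`` where each
    anchor is itself an index blend; ``anchor_b`` is None when only index
    refinement (or no refinement) was performed, in which case ``alpha`` is 0.
    """

    anchor_a: IndexBlend
    anchor_b: IndexBlend | None
    alpha: float
    objective: float
    iterations: int = 0

    @property
    def provenance(self):
        """(c1, k1, c2, k2, alpha) summary; duplicates anchor_a when unpaired."""
        b = self.anchor_b if self.anchor_b is not None else self.anchor_a
        return (self.anchor_a.c, self.anchor_a.k_a, b.c, b.k_a, self.alpha)

    def advance(self, steps: int, lengths) -> "InterpolationResult":
        a = self.anchor_a.advance(steps, int(lengths[self.anchor_a.c]))
        b = None
        if self.anchor_b is not None:
            b = self.anchor_b.advance(steps, int(lengths[self.anchor_b.c]))
        return replace(self, anchor_a=a, anchor_b=b)

    def rates(self, library) -> np.ndarray:
        xa = self.anchor_a.rates(library)
        if self.anchor_b is None:
            return xa
        return (1.0 - self.alpha) * xa + self.alpha * self.anchor_b.rates(library)

    def behavior(self, library) -> np.ndarray:
        za = self.anchor_a.behavior(library)
        if self.anchor_b is None:
            return za
        zb = self.anchor_b.behavior(library)
        return blend_behavior(za, zb, self.alpha, library.circular_flags)

    def weights(self):
        """Convex weights [(c, k, w), ...] over library states (sum to 1)."""
        out = [(c, k, (1.0 - self.alpha) * w) for c, k, w in self.anchor_a.weights()]
        if self.anchor_b is not None:
            out += [(c, k, self.alpha * w) for c, k, w in self.anchor_b.weights()]
        return [(c, k, w) for c, k, w in out if w != 0.0]


# ---------------------------------------------------------------------------
# Blending helpers
# ---------------------------------------------------------------------------


def circular_blend(a, b, alpha):
    """Blend two angles (radians) across the lesser angle between them."""
    d = np.mod(np.asarray(b) - np.asarray(a) + np.pi, TWO_PI) - np.pi
    return wrap_angle(np.asarray(a) + alpha * d)


def blend_behavior(za, zb, alpha, circular_flags):
    out = (1.0 - alpha) * za + alpha * zb
    circ = np.asarray(circular_flags, dtype=bool)
    if circ.any():
        out = np.where(circ, circular_blend(za, zb, alpha), out)
    return out


# ---------------------------------------------------------------------------
# Objective and Newton's method
# ---------------------------------------------------------------------------


def interpolation_objective(alpha: float, mu1: np.ndarray, mu2: np.ndarray, counts: np.ndarray):
    """Poisson log-likelihood of counts under the blended expected counts.

    ``mu1``/``mu2`` are per-bin expected counts (already floored, so the
    blend is strictly positive and affine in ``alpha``); ``counts`` has the
    same shape.  Returns ``(value, d1, d2)``; the second derivative is
    ``-sum(s * ((mu2 - mu1)/mu)^2) <= 0`` everywhere, so the objective is
    concave.
    """
    mu = (1.0 - alpha) * mu1 + alpha * mu2
    diff = mu2 - mu1
    s = counts
    value = float(np.sum(s * np.log(mu) - mu - gammaln(s + 1.0)))
    ratio = diff / mu
    d1 = float(np.sum(s * ratio - diff))
    d2 = float(-np.sum(s * ratio * ratio))
    return value, d1, d2


def optimize_alpha(
    mu1: np.ndarray,
    mu2: np.ndarray,
    counts: np.ndarray,
    tol: float = 0.01,
    max_iter: int = 10,
):
    """Maximize the blend objective over ``alpha`` in [0, 1] via Newton.

    Starts at 0.5 with iterates clamped to [0, 1]; stops when the iterate
    moves less than ``tol``, saturates at 0 or 1, or after ``max_iter``
    iterations.  A (near-)linear objective is resolved by comparing the two
    endpoints.  Identical candidates return ``alpha = 0``.

    Returns ``(alpha, value, iterations)``.
    """
    mu1 = np.asarray(mu1, dtype=float)
    mu2 = np.asarray(mu2, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if np.array_equal(mu1, mu2):
        v, _, _ = interpolation_objective(0.0, mu1, mu2, counts)
        return 0.0, v, 0

    alpha = 0.5
    iterations = 0
    for _ in range(max_iter):
        iterations += 1
        value, d1, d2 = interpolation_objective(alpha, mu1, mu2, counts)
        if d2 > -1e-12:
            # objective linear in alpha: pick the better endpoint
            v0, _, _ = interpolation_objective(0.0, mu1, mu2, counts)
            v1, _, _ = interpolation_objective(1.0, mu1, mu2, counts)
            alpha = 0.0 if v0 >= v1 else 1.0
            break
        new = alpha - d1 / d2
        new = min(1.0, max(0.0, new))
        moved = abs(new - alpha)
        alpha = new
        if alpha in (0.0, 1.0):
            # saturated: stop only if the boundary is the constrained max
            _, d1b, _ = interpolation_objective(alpha, mu1, mu2, counts)
            if (alpha == 0.0 and d1b <= 0) or (alpha == 1.0 and d1b >= 0):
                break
        elif moved < tol:
            break
    value, _, _ = interpolation_objective(alpha, mu1, mu2, counts)
    return alpha, value, iterations


# ---------------------------------------------------------------------------
# Candidate refinement
# ---------------------------------------------------------------------------


def _mu_history(rate_index, c, k, n_bins, active, rate_floor):
    """Floored per-bin expected counts ``(n_bins, n_active)`` ending at k."""
    hist = rate_index.history(c, k, n_bins - 1)[:, active]
    hist = np.where(np.isnan(hist), rate_floor, hist)
    hist = np.maximum(hist, rate_floor)
    return hist * (rate_index.table.delta_ms / 1000.0)


def _blend_mu(anchor: IndexBlend, rate_index, n_bins, active, rate_floor):
    mu_a = _mu_history(rate_index, anchor.c, anchor.k_a, n_bins, active, rate_floor)
    if anchor.k_b == anchor.k_a:
        return mu_a
    mu_b = _mu_history(rate_index, anchor.c, anchor.k_b, n_bins, active, rate_floor)
    return (1.0 - anchor.alpha) * mu_a + anchor.alpha * mu_b


def _index_refine(c, kp, q, rate_index, counts_act, active, rate_floor, min_grid):
    """Interpolate grid state ``kp`` with its better adjacent grid state."""
    samples = rate_index.grid_samples[c]
    k = int(samples[kp])
    n_bins = counts_act.shape[0]
    neighbors = []
    if kp - 1 >= min_grid:
        neighbors.append(kp - 1)
    if kp + 1 < samples.size:
        neighbors.append(kp + 1)
    if not neighbors:
        blend = IndexBlend(c, k, k, 0.0)
        mu = _mu_history(rate_index, c, k, n_bins, active, rate_floor)
        v, _, _ = interpolation_objective(0.0, mu, mu, counts_act)
        return blend, v, 0
    kp2 = max(neighbors, key=lambda j: q[c][j])
    k2 = int(samples[kp2])
    mu1 = _mu_history(rate_index, c, k, n_bins, active, rate_floor)
    mu2 = _mu_history(rate_index, c, k2, n_bins, active, rate_floor)
    alpha, value, iters = optimize_alpha(mu1, mu2, counts_act)
    return IndexBlend(c, k, k2, alpha), value, iters


def _admissible(c, kp, chosen, policy, rate_index, delta):
    """Is grid state (c, kp) admissible as an additional candidate?"""
    min_sep = policy.min_separation_ms  # grid samples are in ms
    for c0, kp0 in chosen:
        if policy.exclusion_rule == "different_condition":
            if c == c0:
                return False
        elif policy.exclusion_rule == "min_separation":
            if c == c0 and abs(kp - kp0) * delta < min_sep:
                return False
        elif policy.exclusion_rule == "different_library":
            if policy.library_tags[c] == policy.library_tags[c0]:
                return False
    return True


def _select_candidates(best, q, n, policy, rate_index, min_grid):
    """Greedy top-n admissible grid states, best first."""
    delta = rate_index.table.delta_ms
    flat = []
    for c, qc in enumerate(q):
        for kp in range(min_grid, qc.size):
            flat.append((qc[kp], c, kp))
    flat.sort(key=lambda t: (-t[0], t[1], t[2]))
    chosen = [best]
    for _, c, kp in flat:
        if len(chosen) >= n:
            break
        if (c, kp) == best:
            continue
        if _admissible(c, kp, chosen, policy, rate_index, delta):
            chosen.append((c, kp))
    return chosen


def refine_estimate(
    best,
    q,
    rate_index,
    buffer_counts,
    policy: CandidatePolicy,
    library,
    active: np.ndarray | None = None,
) -> InterpolationResult:
    """Refine the selected grid state via interpolation.

    ``best`` is ``(c, k_prime, q_value)`` from the argmax; ``q`` the list of
    per-condition grid log-likelihood arrays; ``buffer_counts`` the
    ``(n_bins, N)`` recent binned counts, oldest first.
    """
    c1, kp1, q_best = best
    if active is None:
        active = np.ones(rate_index.n_neurons, dtype=bool)
    rate_floor = rate_index.table.rate_floor
    min_grid = max(
        rate_index.min_valid_grid_index(),
        buffer_counts.shape[0] - 1,
    )
    k1 = int(rate_index.grid_samples[c1][kp1])

    if policy.mode == "off":
        return InterpolationResult(IndexBlend(c1, k1, k1, 0.0), None, 0.0, q_best)

    counts_act = np.minimum(
        np.asarray(buffer_counts)[:, active], rate_index.table.max_count
    ).astype(float)

    blend1, value1, iters1 = _index_refine(
        c1, kp1, q, rate_index, counts_act, active, rate_floor, min_grid
    )
    if policy.mode == "index":
        return InterpolationResult(blend1, None, 0.0, value1, iters1)

    # condition / library refinement: gather additional candidates
    candidates = _select_candidates((c1, kp1), q, policy.n_candidates, policy, rate_index, min_grid)
    if len(candidates) < 2:
        logger.info("no admissible second candidate; returning index-refined estimate")
        return InterpolationResult(blend1, None, 0.0, value1, iters1)

    refined = [(blend1, value1, iters1)]
    for c, kp in candidates[1:]:
        refined.append(
            _index_refine(c, kp, q, rate_index, counts_act, active, rate_floor, min_grid)
        )

    n_bins = counts_act.shape[0]
    best_result = InterpolationResult(blend1, None, 0.0, value1, iters1)
    for i in range(len(refined)):
        for j in range(i + 1, len(refined)):
            ba, va, ia = refined[i]
            bb, vb, ib = refined[j]
            mu_a = _blend_mu(ba, rate_index, n_bins, active, rate_floor)
            mu_b = _blend_mu(bb, rate_index, n_bins, active, rate_floor)
            alpha, value, iters = optimize_alpha(mu_a, mu_b, counts_act)
            if value > best_result.objective:
                best_result = InterpolationResult(ba, bb, alpha, value, ia + ib + iters)
    return best_result
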