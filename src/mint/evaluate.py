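"""Scoring of decoded behavior and estimated neural states.

Decode R^2 is the coefficient of determination per behavioral variable at a
configurable evaluation resolution (default 5 ms), averaged within named
behavioral groups; circular variables substitute circular distances and the
circular mean in the R^2 definition.  Neural state estimates are scored
with bits/spike (base-2 Poisson log-likelihood improvement over each
neuron's mean rate, normalized by total spikes) and PSTH R^2.  Channel
quality filtering (SNR) and the neuron-dropping robustness harness live
here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .library import TWO_PI

logger = logging.getLogger(__name__)

__all__ = [
    "BehavioralGroup",
    "ScoreReport",
    "r_squared",
    "circular_r_squared",
    "score_decode",
    "bits_per_spike",
    "psth_r_squared",
    "score_state_estimate",
    "snr_filter",
    "neuron_drop_experiment",
]


@dataclass
class BehavioralGroup:
    name: str
    members: list  # variable indices
    circular: list | None = None  # subset of members that are circular

    def __post_init__(self):
        if self.circular is None:
            self.circular = []


@dataclass
class ScoreReport:
    group_r2: dict = field(default_factory=dict)
    group_mae: dict = field(default_factory=dict)
    variable_r2: np.ndarray | None = None
    variable_mae: np.ndarray | None = None
    bits_per_spike: float | None = None
    bits_per_spike_per_neuron: np.ndarray | None = None
    psth_r2: float | None = None
    psth_r2_per_neuron: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x

        return {
            "group_r2": {k: conv(v) for k, v in self.group_r2.items()},
            "group_mae": {k: conv(v) for k, v in self.group_mae.items()},
            "variable_r2": conv(self.variable_r2),
            "variable_mae": conv(self.variable_mae),
            "bits_per_spike": conv(self.bits_per_spike),
            "psth_r2": conv(self.psth_r2),
            "metadata": {k: conv(v) for k, v in self.metadata.items()},
        }


# ---------------------------------------------------------------------------
# Decode scoring
# ---------------------------------------------------------------------------


def r_squared(pred: np.ndarray, truth: np.ndarray) -> float:
    """Coefficient of determination; NaN when the truth has zero variance."""
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    ss_res = np.sum((truth - pred) ** 2)
    ss_tot = np.sum((truth - truth.mean()) ** 2)
    if ss_tot == 0:
        return float("nan")
    return float(1.0 - ss_res / ss_tot)


def _circ_dist(a, b):
    return np.mod(a - b + np.pi, TWO_PI) - np.pi


def _circ_mean(theta):
    return np.angle(np.mean(np.exp(1j * np.asarray(theta))))


def circular_r_squared(pred: np.ndarray, truth: np.ndarray) -> float:
    """R^2 with circular distances and the circular mean substituted."""
    d = _circ_dist(np.asarray(pred), np.asarray(truth))
    m = _circ_mean(truth)
    d0 = _circ_dist(truth, m)
    ss_tot = np.sum(d0**2)
    if ss_tot == 0:
        return float("nan")
    return float(1.0 - np.sum(d**2) / ss_tot)


def score_decode(
    decoded: np.ndarray,
    truth: np.ndarray,
    groups: list | None = None,
    circular_flags=None,
    resolution_ms: int = 5,
    valid: np.ndarray | None = None,
) -> ScoreReport:
    """Score decoded behavior ``(M, T)`` against the truth.

    Samples are taken every ``resolution_ms`` (sample-taking, not
    averaging); ``valid`` optionally masks warm-up samples out of the
    evaluation.
    """
    decoded = np.asarray(decoded, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if decoded.shape != truth.shape:
        raise ValueError("decoded and truth must share shape (M, T)")
    M, T = decoded.shape
    if circular_flags is None:
        circular_flags = np.zeros(M, dtype=bool)
    circular_flags = np.asarray(circular_flags, dtype=bool)
    keep = np.zeros(T, dtype=bool)
    keep[::resolution_ms] = True
    if valid is not None:
        keep &= np.asarray(valid, dtype=bool)

    var_r2 = np.empty(M)
    var_mae = np.empty(M)
    for m in range(M):
        p, y = decoded[m, keep], truth[m, keep]
        if circular_flags[m]:
            var_r2[m] = circular_r_squared(p, y)
            var_mae[m] = float(np.mean(np.abs(_circ_dist(p, y))))
        else:
            var_r2[m] = r_squared(p, y)
            var_mae[m] = float(np.mean(np.abs(p - y)))

    report = ScoreReport(
        variable_r2=var_r2,
        variable_mae=var_mae,
        metadata={"resolution_ms": resolution_ms, "n_samples": int(keep.sum())},
    )
    if groups is None:
        groups = [BehavioralGroup("all", list(range(M)))]
    for g in groups:
        report.group_r2[g.name] = float(np.mean(var_r2[list(g.members)]))
        report.group_mae[g.name] = float(np.mean(var_mae[list(g.members)]))
    return report


# ---------------------------------------------------------------------------
# Neural state scoring
# ---------------------------------------------------------------------------


def _poisson_ll(counts, mu):
    mu = np.maximum(mu, 1e-12)
    return counts * np.log(mu) - mu - gammaln(counts + 1.0)


def bits_per_spike(rate_estimates: np.ndarray, spike_counts: np.ndarray, bin_ms: float):
    """Per-spike base-2 log-likelihood improvement over mean rates.

    ``rate_estimates`` (spikes/s) and ``spike_counts`` are ``(N, B)`` over
    evaluation bins of width ``bin_ms``.  The null model is each neuron's
    mean observed count.  Returns ``(overall, per_neuron)``; neurons with
    zero spikes get NaN per-neuron values, and the overall value is NaN if
    no spikes were observed at all.
    """
    est = np.asarray(rate_estimates, dtype=float) * (bin_ms / 1000.0)
    s = np.asarray(spike_counts, dtype=float)
    if est.shape != s.shape:
        raise ValueError("estimates and spikes must share shape")
    null = np.repeat(s.mean(axis=1, keepdims=True), s.shape[1], axis=1)
    ll_model = _poisson_ll(s, est).sum(axis=1)
    ll_null = _poisson_ll(s, null).sum(axis=1)
    nspk = s.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_neuron = (ll_model - ll_null) / np.log(2.0) / nspk
    per_neuron = np.where(nspk > 0, per_neuron, np.nan)
    total_spikes = nspk.sum()
    if total_spikes == 0:
        logger.warning("zero total spikes; bits/spike undefined")
        return float("nan"), per_neuron
    overall = float((ll_model - ll_null).sum() / np.log(2.0) / total_spikes)
    return overall, per_neuron


def psth_r_squared(rate_estimates: list, spike_counts: list, conditions, sigma_ms: float = 30.0):
    """R^2 between trial-averaged rate estimates and empirical PSTHs.

    ``rate_estimates``/``spike_counts`` are per-trial ``(N, T)`` arrays
    (rates in spikes/s, counts at 1 kHz) with a condition label per trial.
    Returns ``(mean_r2, per_neuron_r2)``.
    """
    from .library import gaussian_filter_spikes

    conditions = np.asarray(conditions)
    est_psth, emp_psth = [], []
    for c in np.unique(conditions):
        idx = np.where(conditions == c)[0]
        est_psth.append(np.mean([rate_estimates[i] for i in idx], axis=0))
        emp_psth.append(
            np.mean([gaussian_filter_spikes(spike_counts[i], sigma_ms) for i in idx], axis=0)
        )
    est = np.concatenate(est_psth, axis=1)
    emp = np.concatenate(emp_psth, axis=1)
    per_neuron = np.array([r_squared(est[n], emp[n]) for n in range(est.shape[0])])
    return float(np.nanmean(per_neuron)), per_neuron


def score_state_estimate(
    rate_estimates,
    spike_counts,
    bin_ms: float,
    conditions=None,
) -> ScoreReport:
    """Bits/spike (always) and PSTH R^2 (when condition labels are given).

    Accepts ``(N, B)`` arrays (pooled bins) or per-trial lists; per-trial
    input at 1 kHz is binned internally for bits/spike.
    """
    if isinstance(rate_estimates, (list, tuple)):
        from .likelihood import bin_spikes

        # bin rates by averaging, spikes by summing
        est_b = np.concatenate(
            [
                bin_spikes(np.asarray(r), int(bin_ms))[0] / int(bin_ms)
                for r in rate_estimates
            ],
            axis=1,
        )
        cnt_b = np.concatenate(
            [bin_spikes(np.asarray(s), int(bin_ms))[0] for s in spike_counts], axis=1
        )
        bps, per = bits_per_spike(est_b, cnt_b, bin_ms)
    else:
        bps, per = bits_per_spike(rate_estimates, spike_counts, bin_ms)
    report = ScoreReport(
        bits_per_spike=bps,
        bits_per_spike_per_neuron=per,
        metadata={"bin_ms": bin_ms},
    )
    if conditions is not None and isinstance(rate_estimates, (list, tuple)):
        mean_r2, per_r2 = psth_r_squared(rate_estimates, spike_counts, conditions)
        report.psth_r2 = mean_r2
        report.psth_r2_per_neuron = per_r2
    return report


# ---------------------------------------------------------------------------
# Channel filtering and robustness
# ---------------------------------------------------------------------------


def snr_filter(
    trial_rates: list,
    trial_conditions,
    threshold: float = 2.0,
    sd_floor: float = 5.0,
):
    """Retain channels whose trial-averaged rate range exceeds residual noise.

    ``trial_rates`` are per-trial ``(N, T)`` filtered rates.  SNR is the
    range of the trial-averaged rate divided by the residual SD (floored at
    ``sd_floor`` spikes/s); channels with SNR > ``threshold`` are retained.
    Returns ``(mask, snr)``.
    """
    trial_conditions = np.asarray(trial_conditions)
    N = trial_rates[0].shape[0]
    avg = {}
    for c in np.unique(trial_conditions):
        idx = np.where(trial_conditions == c)[0]
        avg[c] = np.mean([trial_rates[i] for i in idx], axis=0)
    rng_lo = np.full(N, np.inf)
    rng_hi = np.full(N, -np.inf)
    for c, a in avg.items():
        rng_lo = np.minimum(rng_lo, a.min(axis=1))
        rng_hi = np.maximum(rng_hi, a.max(axis=1))
    residuals = np.concatenate(
        [trial_rates[i] - avg[trial_conditions[i]] for i in range(len(trial_rates))], axis=1
    )
    sd = np.maximum(residuals.std(axis=1), sd_floor)
    snr = (rng_hi - rng_lo) / sd
    return snr > threshold, snr


def neuron_drop_experiment(
    decoder_factory,
    library,
    test_streams: list,
    test_truths: list,
    counts_grid,
    repeats: int = 5,
    mode: str = "known",
    seed: int = 0,
    resolution_ms: int = 5,
):
    """Decoding performance as neurons are lost.

    For each retained-neuron count in ``counts_grid`` and each repeat, a
    random subset of neurons is dropped.  In ``known`` mode the decoder
    masks them (equivalent to removal); in ``undetected`` mode their spikes
    are zeroed in the test streams only.  Returns a dict with mean/sd R^2
    curves (averaged over behavioral variables).
    """
    if mode not in ("known", "undetected"):
        raise ValueError(f"unknown mode {mode!r}")
    N = library.n_neurons
    counts_grid = list(counts_grid)
    if any(k > N or k < 1 for k in counts_grid):
        raise ValueError(f"counts grid must lie in [1, {N}]")
    rng = np.random.default_rng(seed)
    means, sds, all_scores = [], [], []
    for n_keep in counts_grid:
        scores = []
        for _ in range(repeats):
            keep = np.sort(rng.choice(N, size=n_keep, replace=False))
            mask = np.zeros(N, dtype=bool)
            mask[keep] = True
            dec = decoder_factory()
            r2s = []
            for stream, truth in zip(test_streams, test_truths):
                if mode == "known":
                    dec.set_active_neurons(mask)
                    res = dec.decode(stream)
                else:
                    z = stream.copy()
                    z[~mask] = 0
                    res = dec.decode(z)
                rep = score_decode(
                    res.behavior, truth, resolution_ms=resolution_ms, valid=res.valid
                )
                r2s.append(np.nanmean(rep.variable_r2))
            scores.append(float(np.mean(r2s)))
        means.append(float(np.mean(scores)))
        sds.append(float(np.std(scores)))
        all_scores.append(scores)
    return {
        "counts": counts_grid,
        "mean_r2": np.array(means),
        "sd_r2": np.array(sds),
        "scores": all_scores,
        "mode": mode,
    }
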