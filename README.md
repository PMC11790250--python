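# mint-decoder

Maximum-likelihood decoding of behavior from neural population spiking over
a library ("mesh") of idealized neural trajectories.

The decoder holds paired libraries of neural trajectories (per-condition
firing-rate matrices, spikes/s at 1 kHz) and behavioral trajectories.  At
runtime, spikes are counted in bins (default 20 ms); the Poisson
log-likelihood of the recent spiking history is evaluated for every
candidate library state via a precomputed, clipped log-likelihood lookup
table and a recursive per-bin update over a downsampled state grid.  The
most likely state is then refined by Newton's method over convex
combinations of two candidate states' rate histories (the objective is
concave in the mixing coefficient), first along the selected trajectory,
then optionally across trajectories or library sections.  Behavior is read
out directly from the interpolated behavioral states, with
circular-variable-aware blending.  Between bin completions the estimate
advances deterministically along its trajectory, giving millisecond
resolution.

## Layout

| module | contents |
| --- | --- |
| `mint.library` | trajectory learning: Gaussian filtering, event-aligned extraction, uniform warping, Type I/II trial averaging, PCA smoothing across neurons/conditions, session-section adaptation |
| `mint.likelihood` | lookup table, rate discretization, spike binning, direct and recursive log-likelihoods |
| `mint.interpolate` | concave blend objective, Newton's method, candidate policies, refinement |
| `mint.decoder` | causal/acausal decoding loop, known-loss masking, held-out rate prediction |
| `mint.synthetic` | kinematic-encoding simulations (Poisson / gamma-interval spiking) and a ground-truth trajectory world |
| `mint.evaluate` | decode R² (incl. circular), bits/spike, PSTH R², SNR channel filter, neuron-dropping harness |
| `mint.fileio`, `mint.cli` | HDF5/CSV/YAML IO and the `mint` command line tool |

## CLI

```sh
mint simulate --n-neurons 100 --n-conditions 8 --trials 20 --seed 7 --out sim.h5
mint train    --config cfg.yaml --data sim.h5 --tau 299 --out lib.h5
mint decode   --library lib.h5 --spikes stream.h5 --bin-ms 20 --window-ms 300 \
              --interp condition --candidates 2 --causal --out decode.h5
mint evaluate --decoded decode.h5 --truth truth.h5 --out report.json
```

## Conventions

- Time is integer milliseconds; rates are spikes/s sampled at 1 kHz.
- Library states are addressed by 0-based `(condition, sample)` internally;
  serialization and logs use 1-based condition numbers.
- A state is a valid decoding candidate iff its index `k >= tau` (full
  history).  Count bins are right-aligned: the bin owned by state `k`
  covers samples `k - delta + 1 .. k`.
- Circular behavioral variables are stored in radians on `[0, 2*pi)`;
  degrees are converted at IO boundaries.
- Lookup-table regularization: rates are floored at 1 spike/s before grid
  assignment and table entries are clipped at `ln(1e-6)`.
- bits/spike follows the standard benchmark convention: base-2 Poisson
  log-likelihood improvement over each neuron's mean rate, normalized by
  the total spike count of the evaluated neurons.
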