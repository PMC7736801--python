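# dropread

Analysis toolkit for **droplet-ordered single-molecule DNA sequencing**: a
chemistry in which single dNTPs are cleaved from a trapped template strand
in sequence order (pyrophosphorolysis) and captured by a stream of
microdroplets, so that droplet acquisition order carries the base order.
The package provides the full computational chain for such runs —

* a **stochastic simulator** of droplet streams: truncated-Poisson capture
  of consecutive template bases (`k ~ Poisson(0.455)` by default, the
  operating point at which 21 % of occupied droplets are multi-base),
  per-droplet per-colour contamination (3.1 % default), channel
  misidentification (0.1 %), and two-component log-normal intensities
  calibrated so the component overlap yields < 0.1 % false positives and
  1.6 % false negatives per colour at the crossing point;
* **occupancy calling**: per-channel two-component mixture fits on log10
  intensity by EM, posterior-threshold calls (tie -> unoccupied), crossing
  points, and overlap FP/FN estimates as component tail masses;
* **read reconstruction**: ordered multiset reads (`SetRead`) in which
  multi-base droplets keep their contents but lose internal order, uniform
  resolution draws, and a best-order search against a reference;
* **alignment**: Smith-Waterman with affine gaps (match +2, mismatch −2,
  gap open −3, gap extend −1; gap of length L costs 3 + (L−1); identity =
  matches / columns, gaps included), with the permutation-averaged mean
  identity over 20 draws as the headline accuracy;
* **5-methylcytosine classification** on two-channel plates (channel 2 is
  blocked by the methyl mark): (−,−) empty, (+,+) dCTP, (+,−) 5mdCTP,
  (−,+) inconsistent (flagged, retained);
* **local GC profiling** by Gaussian smoothing (σ = 20 bases) of the G/C
  indicator.

It is written for method developers who need a faithful, seeded stand-in
for droplet-array runs and a tested reference implementation of the
analysis itself. See `docs/methods.md` for the model and its assumptions.

## Worked example

```python
from dropread import (SimConfig, make_reference, simulate_release,
                      render_intensities, fit_mixture, call_occupancy,
                      droplets_to_read, mean_identity, best_order_search,
                      DEFAULT_CHANNEL_MAP)

reference, _ = make_reference(length=300, gc_target=0.5, seed=1)
cfg = SimConfig(n_droplets=2000, seed=2)          # calibrated defaults
truths = simulate_release(reference, cfg)
records = render_intensities(truths, cfg.intensity_model, seed=3)

fits = {ch: fit_mixture([r.intensity[ch] for r in records])
        for ch in cfg.channels}
calls = call_occupancy(records, fits)
read = droplets_to_read(calls, DEFAULT_CHANNEL_MAP)

summary = mean_identity(read, reference, n_draws=20, seed=4)
_, best = best_order_search(read, reference, seed=4)
print(f"occupied droplets: {len(read)}")
print(f"mean identity over 20 draws: {summary.mean:.3f} ± {summary.sd:.3f}")
print(f"best-order identity: {best.identity:.3f}")
```

prints (seeds as above):

```
occupied droplets: 458
mean identity over 20 draws: 0.737 ± 0.012
best-order identity: 0.806
```

458 droplets were called occupied (template captures plus contaminants);
averaging the alignment identity over 20 random resolutions of multi-base
droplet order gives 0.74, and resolving each multi-base droplet in the
order that best fits the reference raises it to 0.81 — the gap between the
two is the cost of losing within-droplet order.

The same chain is available as numbered drivers under `analysis/`
(simulate → fit/call → blank arrays → reconstruct/align → methylation
plate → GC profiles), each writing its tables under `results/`, and as a
CLI (`dropread simulate|fit|call|reconstruct|align|methyl|gc|pipeline`).

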