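# specdenoise

Intensity-based denoising, GNPS-style similarity scoring and molecular-network
diagnostics for MS/MS (tandem mass spectrometry) fragmentation spectra.

## The problem

Fragmentation spectra carry low-intensity background ions (electronic noise,
co-isolated contaminants) alongside the true fragment ions of the selected
precursor. Because the modified-cosine / GNPS similarity score normalizes over
*all* peaks, background ions that match nothing in the partner spectrum dilute
the score: noisy replicate scans of the same compound can score poorly, and
molecular networks (graphs linking spectra by similarity) accumulate false
structure. The common remedy — removing every ion below a fixed percentage
(often 5%) of the base-peak intensity — is a blunt instrument: in many data
sets a large share of the *structurally informative* ions are themselves
low-intensity, and an aggressive cutoff both discards them and collapses the
network (distinct compounds become indistinguishable).

`specdenoise` implements, for people building spectral libraries and molecular
networks:

* **A tailored, per-spectrum noise filter.** Order the ions of one spectrum by
  increasing intensity; background ions drawn from a roughly uniform intensity
  distribution form a straight line in that ordering, while true fragments
  deviate upward. Fit a robust linear model (Huber M-estimation) of intensity
  on rank over the lowest 75% of ions, compute the residual standard deviation
  s, and cut at the least intense ion exceeding the trend line by more than
  3s. If no ion exceeds the boundary the spectrum is kept unchanged. The
  filter adapts to each spectrum's actual noise level and needs no reference
  material.
* **Baselines**: the absolute percentage cutoff (threshold = p × base-peak
  intensity) and consensus spectra (ions present in ≥ 70% of ≥ 3 replicate
  scans).
* **GNPS-style similarity** with neutral-loss matching: peaks pair either
  directly (|m/z_a − m/z_b| ≤ 0.01 Da) or shifted by the precursor difference
  (|Δm/z − Δprecursor| ≤ 0.01 Da); intensities are square-root transformed and
  unit-normalized; a greedy descending-weight assignment uses each peak at most
  once; the score is Σ of matched weight products ∈ [0, 1].
* **Network diagnostics**: zero-threshold molecular networks, the minimum
  spanning tree (MST) of the distance graph d = 1 − s, and
  **M(d_5%)** — the median of the lowest fifth percentile of MST edge
  distances. M(d_5%) → 0 signals network collapse.
* **A data-dependent optimal cutoff**: sweep cutoffs 0–10%, track the fraction
  of structurally explained ions removed (rising) against M(d_5%) normalized to
  its cutoff-0 value (falling); the grid point nearest the crossing balances
  ion retention against collapse.
* **A synthetic-spectrum generator** with planted ground truth (fragment vs.
  background labels, explained flags, compound families with shared fragments,
  replicate scans with instrumental jitter) used throughout the test suite.

## Worked example

```python
from specdenoise import (SynthConfig, generate_library, tailored_denoise,
                         similarity_matrix, mst, sweep, optimal_cutoff)

library = generate_library(SynthConfig.network_benchmark(seed=42))
spectrum = library[0]
result = tailored_denoise(spectrum)
print(f"{spectrum.id}: kept {result.keep.sum()} of {len(spectrum)} peaks "
      f"(threshold {result.threshold_intensity:.4f})")

raw_tree = mst(similarity_matrix(library))
print(f"raw network: M(d_5%) = {raw_tree.m_d5:.3f}, zero distances = {raw_tree.zero_count}")

curves = sweep(library)
print(f"optimal cutoff = {100 * optimal_cutoff(curves):.2f}% of base-peak intensity")
erf_t, md5_t = curves.tailored_point
print(f"tailored filter: {100 * erf_t:.1f}% explained ions removed, M(d_5%) = {md5_t:.3f}")
```

prints

```
C000_R0: kept 13 of 99 peaks (threshold 0.0366)
raw network: M(d_5%) = 0.167, zero distances = 0
optimal cutoff = 3.25% of base-peak intensity
tailored filter: 0.0% explained ions removed, M(d_5%) = 0.073
```

Reading: the filter kept the 13 true fragment ions of a 99-peak spectrum,
cutting at 3.7% of the base peak — adapted to this spectrum's noise, below the
5% convention. On this 50-compound benchmark the sweep places the optimal
cutoff at 3.25%; at that point the two curves cross. The tailored filter
removes **no** structurally explained ions (a blanket 5% cutoff removes ~52%
of them here) while compacting the network (M(d_5%) 0.167 → 0.073).

A command-line interface mirrors the library:

```sh
specdenoise simulate lib.mgf --seed 42 --labels labels.tsv
specdenoise tailored lib.mgf clean.mgf --quantile 0.75 --ksd 3
specdenoise score-matrix clean.mgf matrix.csv
specdenoise mst clean.mgf tree.tsv --report
specdenoise sweep lib.mgf report.csv --explained labels.tsv
```

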