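# Methods

## The tailored noise filter

**Model.** A fragmentation spectrum is assumed to be a mixture of background
ions whose intensities follow an approximately uniform distribution and true
fragment ions with larger intensities. Under that assumption the sorted
intensity sequence of the background is, in expectation, linear in rank
(uniform order statistics), so the background appears as a straight line when
ions are ordered by increasing intensity, and fragments bend the curve upward.

**Procedure.** For a spectrum with N ≥ 4 peaks:

1. sort peaks by increasing intensity, ties broken by ascending m/z (stable,
   deterministic); assign ranks r = 1..N;
2. fit intensity ~ a + b·r over ranks 1..⌈q·N⌉ by a robust linear model
   (Huber M-estimation via iteratively reweighted least squares, tuning
   constant 1.345 — the conventional default giving 95% efficiency under
   normal errors); q defaults to 0.75;
3. compute s = SD (ddof 1) of the RLM residuals over the fitted subset;
4. the upper boundary at rank r is a + b·r + k·s with k = 3;
5. if no ion exceeds its boundary, keep the spectrum unchanged; otherwise
   set the threshold to the minimum intensity among boundary-exceeding ions
   and keep every ion with intensity ≥ threshold.

Spectra with fewer than 4 peaks pass through unchanged (a line fit is
meaningless); an RLM failure falls back to ordinary least squares with a
logged warning. The filter is invariant to uniform intensity rescaling: ranks
are unchanged, and the fit, residual SD and boundary all scale linearly.

**Numerical choices.** Exceedance uses a relative guard
(intensity > boundary + 1e-9 × max intensity): when the background is exactly
linear the residual SD underflows and raw float noise in the fitted
coefficients would otherwise flag on-the-line ions. A spectrum with all-equal
intensities short-circuits to the constant fit with zero residuals and is
always kept unchanged.

**Open choices, resolved.** With increasing-intensity ranks, "the last
exceeding ion" read literally would be the most intense ion, and cutting
there would discard nearly the whole spectrum; the implemented rule — cut at
the *least* intense exceeding ion — is the only reading under which the kept
set is the high-intensity tail. The alternative remains available via
`TailoredConfig(cut_at_last_exceeding=True)`. Likewise the residual SD is
taken over the fitted subset (residuals of a model are defined where it was
fitted); `sd_on_all=True` switches to all peaks.

## Baselines

The **percentage cutoff** removes ions strictly below p × base-peak
intensity (an ion exactly at the threshold is kept); it is monotone: a larger
p keeps a subset of what a smaller p keeps. The **consensus spectrum**
requires ≥ 3 replicate scans of one compound (same polarity, precursors
within tolerance), pools peaks, groups them by single-linkage on the sorted
m/z axis (gap > 0.01 Da splits), and retains groups present in ≥ 70% of
scans; consensus m/z is the intensity-weighted group mean, consensus
intensity the mean of member intensities. The 0.01 Da grouping tolerance
matches the similarity tolerance; no independent value is established for it.

## Similarity

The GNPS-style score square-root transforms intensities, normalizes each
spectrum's transformed vector to unit Euclidean norm, enumerates candidate
pairs matched directly (|Δm/z| ≤ 0.01 Da) or by neutral loss
(|Δm/z − Δprecursor| ≤ 0.01 Da; a pair qualifying both ways counts once), and
selects a one-to-one assignment greedily by descending weight
(weight = product of the two normalized intensities). The score is the sum of
selected weights, clamped to [0, 1].

Greedy ties are broken on the *sorted* m/z pair of the candidate — the
minimal rule that is invariant under swapping the two spectra, which makes
the score exactly symmetric. An exact maximum-weight assignment
(`assignment="optimal"`) is available and is cross-checked against an
exhaustive enumeration in the tests; greedy equals the optimum whenever
candidate pairs do not conflict, which is the typical case at 0.01 Da
tolerance. The square-root transform and the greedy resolution follow the
convention of the widely used reference implementations; both are
config-exposed (`sqrt_transform`, `assignment`). Tolerances are absolute Da
throughout, not ppm.

Because each spectrum's normalization runs over all of its peaks, adding
ions that match nothing in the partner spectrum strictly lowers the score.
This single property drives every noise effect the package measures.

## Networks and collapse statistics

Similarity matrices are built per ionization mode. Molecular-network edges
use zero thresholding by default (every strictly positive similarity). The
MST is computed on the *complete* distance graph d = 1 − s (zero-similarity
pairs enter at distance 1) so the tree spans all spectra; Kruskal's algorithm
with edges pre-sorted lexicographically by id pair is deterministic under
ties, and the MST weight multiset is unique regardless of tie-breaking.
M(d_5%) takes the lowest ⌈0.05·(n−1)⌉ tree distances and returns their
median (midpoint for even counts). Zero distances are counted with an
absolute guard of 1e-12 to absorb float noise from scores clamping to 1.

## The data-dependent optimal cutoff

The sweep evaluates cutoffs 0, 0.25%, …, 10% (41 points; the grid spacing is
a resolution choice, not a measured quantity). At each cutoff every spectrum
is denoised, the similarity matrix and MST recomputed, and three quantities
recorded: the pooled fraction of explained ions removed (ion-weighted across
spectra, not averaged per spectrum — spectra with many explained ions should
weigh more), M(d_5%), and the zero-distance count. The tailored filter is
evaluated once alongside.

The two curves live on different scales; M(d_5%) is normalized by its
cutoff-0 value so both lie in [0, 1] ( `normalization="minmax"` is the
config-exposed alternative). The optimal cutoff is the grid point minimizing
the absolute gap between the curves, ties to the smaller cutoff. The whole
workflow is invariant to uniform intensity rescaling of the input spectra.

## The synthetic generator

Each compound's spectrum contains three planted populations, intensities
relative to a base peak of 1:

* **family core fragments** — m/z shared within a compound family (the first
  ⌈0.4·k⌉ of a family pool, so any same-family pair shares its core),
  intensities 0.35–1.0 from a family-level pattern with 10% CV per-compound
  variation; these model the class-determining fragments of structurally
  related compounds;
* **compound-unique fragments** — log-normal relative intensities (defaults:
  median 0.10, σ 0.5, clipped to [0.07, 0.30]); these carry the
  compound-specific information;
* **background ions** — count uniform in [60, 100], intensities uniform on
  (0, 0.05] of the base peak, m/z uniform with an exclusion margin around
  true peaks so background never matches across spectra.

Replicate scans add multiplicative log-normal intensity jitter (CV 15%) and
Gaussian m/z jitter (SD 0.002 Da) — invented instrumental-variability values
of realistic magnitude. All draws flow from one `numpy` Generator, so a seed
fixes the library bit-for-bit. The default configuration (50 compounds × 4
replicates = 200 spectra, 10 families, seed 42) is the benchmark for
denoising recovery and homologous-pair scoring.

`SynthConfig.network_benchmark()` is the second study condition, built for
the collapse analysis: one reference spectrum per compound (networks are
built from reference spectra, not replicate stacks), isomeric families
(shared precursor, so neutral-loss matching coincides with direct matching
within a family), compound-unique ions in a *low* band (log-normal median
0.036 clipped to [0.028, 0.048] of the base peak) above a background topping
out at 1.5%, and library-wide m/z exclusion between all peaks. The regime
encodes the situation the threshold workflow exists for: the informative
compound-specific ions sit below the conventional 5% cutoff, while the true
background sits below them — so an adaptive filter can separate the two and
a blanket 5% cutoff cannot. The library-wide exclusion makes every
background and compound-unique ion match-free across spectra; removing a
match-free peak can only increase a pairwise score, so all pairwise
distances are monotone in the cutoff, and because the sorted MST weight
vector is elementwise minimal over spanning trees, M(d_5%) and the
zero-distance count are then *exactly* monotone across the sweep rather than
only in trend.

**What the generator does not emulate:** chemically structured noise
(isotope satellites, co-isolation of related precursors), intensity-dependent
m/z error, detector saturation, or background whose intensity distribution
overlaps the fragment range. Passing the planted-truth tests therefore shows
that each procedure implements its contract and behaves as designed under
the stated noise model — not that the same retention/removal rates will hold
on instrument data, where the background assumption must be checked per
setup (e.g. by inspecting rank-ordered intensity plots).

The noise-injection experiment draws, per simulation, one full set of 100
artificial ions (intensities uniform on (0, 5%] of base, m/z excluded around
existing peaks) and reveals it in increments of 5, so each simulation trace
is nested and strictly decreasing; means are taken over 100 simulations.
Spectra with few fragments degrade faster because their base peak is a
larger share of total intensity, so the same additive noise budget is larger
relative to their norm.

## Library curation

Spectra enter a library only if spectral entropy < 3 (Shannon entropy,
natural log, of intensities normalized to sum 1 — raw intensities, no
transform, matching the standard spectral-entropy definition), ion count
strictly between 20 and 1000, and — where explained flags exist — explained
ratio < 0.75 (a nearly fully explained spectrum has usually been curated
already). All comparisons are strict. MGF I/O is delegated to pyteomics;
peaks are re-sorted on read, exact duplicate m/z merged by summing
(logged), polarity taken from IONMODE, else the CHARGE sign; peak values are
written with 12 significant digits (round trip lossless below 1e-9 relative)
and the precursor with `repr` (exact text round trip).

## Problem sizes

The shipped benchmarks are sized for a laptop-class single core: 200 spectra
(recovery/homologous experiments), 50 spectra × 42 network rebuilds (sweep),
100 × 21 scorings (noise injection); the acceptance script completes in
under a minute. All sizes are configuration values and scale up unchanged.

## Known limitations

* The RLM filter presumes the uniform-background / prominent-fragment
  structure; spectra violating it (e.g. chimeric spectra, background with
  heavy-tailed intensities) can lose genuine low-intensity fragments, and
  nothing in a single spectrum can reveal that.
* Consensus creation requires ≥ 3 replicates and errors otherwise — by
  design, since silently passing through a single scan would misrepresent
  the method.
* The greedy assignment can undershoot the optimal matching when candidate
  pairs conflict (dense spectra, coarse tolerance); the optimal assignment is
  available but quadratic-cubic in peak count.
* m/z tolerances are absolute; very high-mass fragments would warrant ppm.
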