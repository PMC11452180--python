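# Methods notes

## Model and assumptions

PCCD is a purely geometric birth-order inference: it assumes that within a
specimen the Euclidean distance of a motoneuron from its neuroblast (NB) is a
monotone proxy for age (furthest = oldest), that this relation is noisy at
the single-cell level but consistent across specimens, and that a TF is
expressed in one or a few *contiguous* birth-order windows. Everything
downstream of ranking is strictly one-dimensional; no spatial structure
beyond the distance is used, and no statistical test is attached to a
cluster call.

Cell tables are long-format TSV/CSV (`specimen_id, cell_id, class, x_um,
y_um, z_um, tf, call`). A missing call means *not assessed* and is never
collapsed to "off": a cell without a call for a TF is simply absent from
that TF's sequence, and a specimen that never stained a TF contributes to no
at-risk count `Nᵢ` for it. This censoring-aware bookkeeping is what makes
the relative frequency `Pᵢ/Nᵢ` unbiased under random truncation of observed
sequence length — the global alternative `Pᵢ/N` equals `(Pᵢ/Nᵢ)·(Nᵢ/N)`
identically and is therefore biased low at deep ranks exactly by the at-risk
fraction.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `smoothing.window` | 11 ranks | Savitzky–Golay window |
| `smoothing.polyorder` | 3 | local polynomial degree |
| `peaks.h_min` | 0.2 | minimal smoothed frequency of a peak |
| `peaks.d_min` | 8 ranks | minimal separation between retained peaks |
| `peaks.p_min` | 0.07 | minimal prominence (drop to the key saddle) |
| `clusters.max_birth_order` | 29 | survivor count defining the code axis |

Peak detection uses `scipy.signal.find_peaks` semantics throughout: interior
local maxima only, plateaus represented by their midpoint sample, filters
applied in the order height → distance (candidates ranked by height, the
lower of two near candidates dropped) → prominence. The test suite pins this
against an independent O(L²) brute force that computes prominence by
explicit contour descent. When two candidates have *exactly* equal heights
the keep-order under the distance filter is an implementation detail and is
deliberately left unspecified.

## Numerical conventions and degenerate inputs

* **Ranks** are 1-based; all intervals are closed `[a, b]`.
* **Ties in distance** are broken by ascending `cell_id`, then input order,
  so rankings are deterministic. Apoptotic cells are excluded from
  sequences unless explicitly included.
* **Smoothing edges** use the interpolating convention: a single
  degree-`polyorder` polynomial is fitted to the first/last window and
  evaluated at the edge ranks (`mirror` is available as an alternative).
  Zero-padding would suppress exactly the NB-proximal clusters the analysis
  is about. Sequences shorter than the window shrink it to the largest odd
  number ≤ L (polyorder capped at window−1); length-1 profiles pass through
  unsmoothed. Smoothed values are clipped to [0, 1], since frequencies are
  probabilities and the filter can overshoot at sharp steps.
* **Region boundaries** between adjacent peaks sit at the minimum of the
  smoothed profile strictly between them; a tied (flat) valley is cut at its
  midpoint rank, and the boundary rank joins the left region. Regions tile
  the axis exactly.
* **Cluster placement** formalizes "the horizontal span under the peak
  covering n cells" as an interpolated level-set descent: the cut level is
  found by bisection (the width of the component containing the peak is
  monotone in the level), widths count cells as `x_right − x_left + 1` with
  linear interpolation between ranks, and the component is clipped to the
  peak's region. Fully covered integer ranks form the core span; the
  fractional remainder `n − core` is split across the two border ranks in
  proportion to the interpolated overhang on each side, so coverages sum to
  `n` to 1e-9. `n` is kept real-valued — rounding would break that
  conservation and discard the border information the dashed coverage index
  conveys. `n = 0` yields an empty call; `n < 1` puts all its coverage on
  the peak rank; `n` beyond the region's capacity saturates the region at
  coverage 1 per rank with a warning (`saturated` flag set).
* **Reported integer spans** (`called_span`) are the majority-covered ranks
  (coverage ≥ 0.5). This matters near the axis edges, where the asymmetry of
  the polynomial edge fit can shift the cut level by a few hundredths of a
  rank and produce ~0.04 fractional borders even on noise-free data; the
  majority rule renders the cluster bar a reader would draw. The fractional
  detail is always preserved in `coverage`.
* **Mean positive count** `n` is the plain mean over sequences of the number
  of positive calls at *observed* ranks inside the region; sequences too
  short to reach the region still count in the denominator.
* **Supernumerary ranks** beyond `max_birth_order` (larval cells destined
  for programmed cell death) are kept in a separate annex of the code map
  rather than being rescaled onto the 1–29 axis.

## What the synthetic generator emulates — and what it does not

Specimens are built as: NB at the origin; the k-th born of `n_mn`
motoneurons at radius `d0 + step·(n_mn − k)` (defaults 10 µm + 2.5 µm/rank)
plus Gaussian positional noise (default SD 0.75 µm, giving ≈1% adjacent-rank
swaps), in a random hemisphere direction; per-specimen counts drawn around
stage presets (larval 39 ± 2, 24 h APF 32 ± 1, adult 29 ± 1); TF calls
Bernoulli(`p_in`, default 0.9) inside planted intervals whose endpoints
jitter by ±1 rank per specimen, Bernoulli(`p_out` = 0.02) outside; optional
uniform truncation of observed length (dropping NB-proximal cells).
Randomness derives from `(seed, specimen index)`, so cohorts are
reproducible and order-independent.

Genotype presets encode the qualitative control vs Imp-overexpression vs
Syp-knockdown contrasts: control plants Jim at ranks 16–23 and RunxA/Nvy
each in an early (5–12) and a last-born (≈28–36) block; the perturbed
presets extend Jim to rank 30/29, delete the last-born RunxA block, and
lower the last-born Nvy block's `p_in` to 0.4. Interval ranks and noise
levels are plausible defaults, not measured quantities.

The generator does **not** model NB division timing, Imp/Syp expression
dynamics, apoptosis, anisotropic tissue growth, segmentation errors, or
spatially correlated staining artefacts. Passing tests therefore demonstrate
that the pipeline recovers contiguous expression windows under radial
geometry with independent per-cell noise and censoring — not that real
imaging data satisfy those assumptions.

## Verification design

* Every operator is pinned to an independent oracle: translation/isometry
  and sorting against brute-force recomputation; the smoother against
  per-window least-squares fits (and exactness on cubics, which a
  degree-3 filter must pass untouched); peak detection against the
  contour-descent brute force on randomized profiles across a parameter
  grid; cluster placement against hand-solved triangular profiles.
* End-to-end: noise-free cohorts must be recovered *exactly* (spans and n)
  for one- and two-block TFs; under realistic noise (p_in 0.9, p_out 0.02,
  ±1 jitter, 20 specimens) recovered boundaries must fall within one rank of
  the planted truth in ≥95% of replicate cohorts.
* The relative-vs-global comparison asserts the algebraic at-risk identity
  exactly and checks the relative estimator against the planted per-rank
  probabilities inside a simultaneous 95% binomial band (Bonferroni-split
  across tested ranks — independent per-rank bands would jointly fail by
  construction).
* Determinism is asserted at the byte level: identical seeds reproduce
  identical report bundles, and table round-trips are lossless.

Problem sizes in the test and acceptance runs (cohorts of 16–20 specimens,
100 replicate cohorts, 500-specimen bias cohorts, 1000-profile oracle
sweeps) are chosen to exercise every code path at the cohort scale the
method targets while keeping the full suite in the seconds range.

## Known limitations

* Cluster calls carry no uncertainty; the coverage index is a deterministic
  rendering convention, not a confidence measure.
* Contiguity is assumed, not tested: a genuinely fragmented expression
  pattern (e.g. salt-and-pepper) will be forced into at most a few clusters
  whose `n` averages over the fragments.
* With fewer than ~15 specimens the relative frequencies are noisy enough
  that peak calls become unstable; the pipeline warns but still runs.
* Exact height ties between peak candidates are resolved by an unspecified
  (library-internal) order; profiles from real cohorts essentially never
  produce them.
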