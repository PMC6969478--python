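# Methods

## The system being modeled

An anostracan (fairy shrimp) larva hatches with a head, three specified
trunk segments (marked by transverse Engrailed/En stripes), an
unsegmented posterior growth zone (GZ), and a terminal telson. New
segments are specified sequentially at the anterior face of the GZ at a
constant rate; the GZ is a shrinking cell field, partially replenished by
a low level of cell division, and the visible elongation of the animal is
dominated by growth of the already-specified segments. The larval
epithelium is a single cell layer attached to the cuticle, which justifies
treating the ventral surface as a 2D nucleus point pattern and neglecting
bulk cell movement.

`gzmorph` reimplements the quantitative side of this picture as a tested
pipeline driven by a synthetic larva generator. The generator is a model
of the *data*, not of the developmental mechanism: it reproduces the
statistical structure a microscopist would score (stripe counts, lengths,
widths, areas, label fractions), so that every estimator in the package
can be validated against known ground truth.

## Staging clock

Stripe count at `t` hours post hatch is
`min(max_stripes, initial_stripes + floor(t / interval_h))` with defaults
3, 17 and 1.4 h. Defaults place the first molt at 3.7 h; the molt adds
`molt_gz_gain_cells = 2.5` cells to the GZ length instantaneously (the
observation is a post-molt length gain; the mechanism is not modeled).
With a 1.4-h interval an 18-h window yields 12 added segments (15
stripes); the cap at 17 is never reached in the default cohort. The
reported "14 segments within 18 h" and the 1.4-h interval are mutually
inconsistent by about 1.6 h; the package follows the interval and leaves
`interval_h` user-settable rather than reconciling silently.

A staged cohort adds three noise sources per larva, all seed-derived:
a segmentation-cycle phase at hatch, uniform on
`[0, phase_jitter_frac · interval_h)`; a hatch-time jitter uniform on
±`hatch_jitter_min/2` (default 15 min, the collection interval); and a
stripe-count observation noise uniform on {−1, 0, +1}. The phase term is
what makes the cohort-level OLS slope an unbiased estimate of
`1/interval_h`: with all larvae at phase zero the floor function aliases
against hourly sampling and biases the slope.

## Field geometry

Nuclei sit on a brick-offset ("hexagonally" staggered) lattice with
nearest spacing `cell_diameter_um` (default 6 µm; the number is a free
parameter — every count↔length conversion goes through it), jittered
uniformly by ≤ 0.2 spacings per coordinate. Per-larva overall size varies
with CV `size_cv = 3 %`. Rows run mediolaterally; each specified segment
owns `base_length + 1` rows, the last row carrying its En stripe label.
Segment base lengths decline with addition order (5×4, 4×3, 5×2 cells for
the 14 added segments), and segments mature after specification
(length/width multiplier `1 + 0.1·age`, capped at 2), which reproduces the
disproportionate growth of anterior segments and an approximate doubling
of body length over the staging window. Body length includes a
nucleus-free head offset (`head_length_um = 200`) chosen so a hatchling
measures ≈ 0.41 mm.

The GZ starts at 13 cells length, width A (at the newest stripe) 22
cells, width B (GZ/telson boundary) 28 cells — numbers chosen as the
consistent factorization that makes the hatchling pool
`13 × (22+28)/2 = 325` cells and the 14 added segments
`22 × (5·4 + 4·3 + 5·2) = 924` cells, hence `log2(924/325) ≈ 1.5`
doublings. GZ length shrinks by 0.6 cells and width B by 0.4 cells per
added segment (fractional lengths are realized by stochastic rounding, so
stage means shrink smoothly); `constant_gz_mode` freezes both, emulating
the *Artemia*-like regime where the GZ is maintained through the first
nine stripes. Width A is constant by construction, matching the
observation that the newest stripe's width barely varies across tagmata.

Landmarks (midline, stripe lines, width A/B lines, lateral margins) are
drawn through nominal (pre-jitter) nucleus positions. Counting corridors
of half-width 0.5 diameters around these lines therefore recover the
configured counts exactly on noiseless fields; the corridor half-width is
a package convention — scoring "along a line" does not define one.

## Cell-cycle labels

Per sub-region (older segments / newest segment / anterior GZ / posterior
GZ / telson) the generator draws, in order: a nuclear-morphology M flag at
exactly the configured mitotic fraction (GZ default 2.5 %, within the
observed 1–4 % range), an independent pH3 flag at `ph3_ratio` (2.4×) that
rate, and S phase among non-mitotic nuclei (band 0.98, posterior GZ 0.35,
anterior GZ 0.02, telson 0.05). The two M markers are independent because
their detection windows (late vs. early M) barely overlap in this species;
they are never a subset relation. Inside the synchronous band both M-flag
probabilities are damped ×0.1, producing the "pH3 typically excluded from
the band" signature. Every mitotic nucleus carries a spindle angle: AP
(uniform 0–45°) with probability 0.8 in the GZ and 0.25 in segments,
otherwise transverse (45–90°).

## Estimators and numerical choices

* **En-stripe scoring**: a stripe counts only if its nuclei form a chain
  from margin to margin; adjacency is an edge-to-edge gap ≤ 1.5 cell
  diameters (center distance ≤ 2.5 diameters), so a single missing cell
  does not break a stripe but scattered cells never score.
* **Orientation**: AP iff angle ≤ 45°, the tie at exactly 45° going to AP
  (the cutoff is a convention; the data motivating it are bimodal).
* **S-phase domains**: sliding window of width 2 cell diameters, step 0.5
  diameters, from just posterior to the penultimate stripe to the
  GZ/telson boundary; windows classified synchronous (≥ 0.8), clear
  (≤ 0.1), else scattered; same-class runs merged; domains narrower than
  one window absorbed into the longer neighbor; each internal boundary is
  then refined to the half-level crossing of the profile, which removes
  the ~window/2 bias a pure threshold rule leaves on a step edge. Detected
  boundaries land within one window (±12 µm) of generator truth.
* **Division budget**: depletion model `log2(N/G0)` by default, chosen
  because the GZ demonstrably shrinks away; the persistence variant is
  reported alongside since the original bookkeeping does not state which
  was used. Both are computed from stage-mean cell counts of a measured
  cohort.
* **Rate fit**: closed-form normal equations (cross-checked against
  `scipy.stats.linregress`), slope SE from residual variance.
* **PCA**: correlation-matrix eigendecomposition of the eight standardized
  measures; component signs fixed so the largest-magnitude loading is
  positive; cross-checked against scikit-learn.
* **Tagma separation**: the parametric MANOVA used on the real data is
  replaced by a permutation test (pseudo-F on PC1–PC3,
  `p = (1 + #{perm ≥ obs}) / (1 + B)`) because the generator's output
  gives no license for the parametric assumptions. Records with stripe
  counts outside 3–17 are excluded from tagma analyses with a warning.
  Tagma regression codes groups 1–4 in axial order.
* **Tukey HSD** via `scipy.stats.tukey_hsd` (closed-form studentized
  range).

Degenerate inputs are first-class: zero-length GZ midlines measure zero,
fields with < 2 stripes flag last-segment measures absent, constant PCA
columns raise an error naming the column, groups with < 2 rows refuse the
permutation test.

## Problem sizes

Default analyses use cohorts of 25 larvae per hourly timepoint over
0–18 h (475 larvae, ~1–3 k nuclei each); pooled label-frequency checks use
50 replicate hatchlings; estimator-recovery checks use 100 replicate
cohorts (staging columns only) and 200 null simulations for the
permutation test's size. These sizes put 3-SE bands comfortably around
the configured rates.

## What passing tests do and do not show

The generator emulates staged scoring of an idealized flat epithelium:
lattice packing with small jitter, exact landmark lines, no segmentation
errors, no curvature, no dorsoventral projection error, no lineage
structure, and the three posterior S-phase classes collapsed into one
"scattered" regime (bilateral clusters are not modeled; the band's
occasional lateral spill into the penultimate segment is off by default).
Tests passing on such fields validate the estimators — that the measures,
domain detector and statistics recover what was put in — not the biology
of any real larva. Conversely, published effect sizes that depend on the
authors' measurement data (PCA variance percentages, the MANOVA F, the
PC1-on-tagma R², per-stage means) are deliberately not asserted anywhere;
the deposited measurement data can be used for external validation but
are never required.
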