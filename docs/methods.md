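# Methods

## Model of the assay

A padlock-probe in situ mutation assay reports each detected transcript as
one rolling-circle product (RCP): a sub-micron ball of concatemeric DNA
carrying many copies of a backbone sequence, visualized by a
fluorophore-labeled detection probe. Because wild-type and mutant padlock
probes carry different backbones, the fluorophore channel of a spot encodes
the allele. The analysis task is therefore: find the spots in each channel,
discard artifacts, count wild-type (w) and mutant (m) spots per tumor area,
and report the mutant allele frequency f̂ = m/(m+w) with its sampling
uncertainty and a comparison against non-neoplastic control tissue.

## Image model and simulator

The simulator renders, per channel, a constant autofluorescence background
plus isotropic Gaussian blobs (σ = `psf_sigma`, default 1.5 px) at
Poisson-sampled locations, followed by Poisson shot noise (additive
Gaussian noise available as an option). Spot counts per region are
Poisson(density × area); locations are uniform over the region mask; each
spot is assigned one z-plane of the stack uniformly. Classes are drawn per
spot: unspecific with probability `unspecific_rate`, otherwise mutant with
the locally applicable mutant fraction (a sub-clonal patch overrides its
parent region's fraction inside the patch). Unspecific spots are rendered
at identical coordinates and z in two distinct non-nuclear channels —
modeling autofluorescent debris visible at multiple wavelengths — while
specific spots appear in exactly one channel. The nuclear channel carries
larger Gaussian "nuclei" blobs unrelated to any spot. The seed fully
determines the output bit for bit.

Key defaults and why:

| parameter | default | rationale |
|---|---|---|
| `spot_amplitude` / `background_level` | 200 / 20 counts | 10× background: a clean assay where the S/B > 2 criterion is the binding constraint only for noise, not for real spots |
| `psf_sigma` | 1.5 px | diffraction-limited spot at desk-scale sampling |
| `unspecific_rate` | 0.015 | matches the ~1.5 % false-positive background the assay shows on non-neoplastic tissue |
| `n_z` | 3 | enough planes that maximum-intensity projection is exercised non-trivially |
| noise | Poisson | shot-noise-limited detection; keeps images integer-valued |

Tumor content is a per-region scalar plus a smooth random field (±0.05,
Gaussian-filtered noise), so field-of-view gating at > 0.8 has spatial
texture to act on; in the real assay this number is a pathologist's
assessment.

The four-area preset (`k386_like_preset`) encodes the study conditions this
package is built around: mutant fractions 0.01/0.01/0.06/0.14 across areas
1–4, a sub-clonal patch at 0.07 inside area 2, and a control region at
0.015. Each area is a 512×1280 px strip that tiles exactly ten 256×256
fields; the density (≈4.6·10⁻⁴ spots/px²) puts ≈300 informative spots in
each area, matching the counted-signal totals the assay produces per area.
These sizes are the package's working scale; they keep a full 20-seed
recovery experiment comfortably on one CPU.

**What the simulator does not emulate:** optical vignetting, chromatic
shift, intensity-dependent bleed-through (artifacts here are all-or-none
two-channel spots), spatially varying autofluorescence, nuclear exclusion
of spots, and cell boundaries. Passing tests therefore show the analysis
logic is correct under a clean, known-truth image model — not that the
detector is robust to every real-microscope pathology.

## Background and detection

"Background" for the S/B ratio is the local windowed median (default
31 px): robust to the sparse spots themselves, local enough to track smooth
autofluorescence, and parameter-light. Borders are handled by mirror
padding (edge pixel not repeated). For unsigned-integer images the median
uses a sliding-histogram rank filter on a pre-padded array — exact for odd
windows on integer data and fast at desk scale; float images use
`scipy.ndimage.median_filter`. Both paths are checked against a brute-force
windowed median.

A candidate spot is a pixel of the Gaussian-smoothed (σ = 1 px) projection
that (a) dominates its Chebyshev neighborhood of radius `min_separation`
(default 3 px, window clipped at borders), (b) is not on a fully flat
window, and (c) is the lexicographically smallest (row, col) of any
equal-valued plateau — a purely local rule, verified against an exhaustive
per-pixel scan. The spot's peak is the *raw* (unsmoothed) intensity at that
pixel; its S/B ratio is peak / background-map value there, and the
inclusion comparison is strict (> 2 for quantification, > 5 for
overviews). Candidates with zero background are dropped with a warning
rather than given infinite ratios. Peak-pixel (not integrated) intensity is
used for the ratio, consistent with a per-pixel intensity criterion.

Known detector limitation: two spots closer than about `min_separation`
merge into one displaced peak. At the preset density this affects ~1 % of
spots; it is the dominant cause of both the ~99 % (not 100 %) recall and
the occasional unspecific spot whose two channel detections end up farther
apart than the coincidence radius.

## Artifact exclusion and classification

Spots within 2 px (Euclidean) of a spot in a *different* non-nuclear
channel are flagged unspecific in all channels involved; matching is
symmetric, idempotent and order-invariant (KD-tree pairwise queries). The
2 px default reflects that genuine RCPs are diffraction-limited: a
coincidence within a PSF width is treated as the same physical object.
Wild-type/mutant coincidences are excluded like any other multi-channel
signal — never arbitrated by intensity. Flagged spots are retained in
tables (class "unspecific") but excluded from both numerator and
denominator of every frequency. Positive-control-channel spots likewise
never enter mutation counts; they only indicate the assay worked.

## Quantification

Fields of view are fixed-size boxes placed on a non-overlapping tiling grid
of the region's bounding box; a placement is eligible if it lies wholly in
the region and its mean tumor content exceeds 0.8, and the requested number
(default 10) is drawn uniformly at random among eligible tiles under the
seed. Restricting candidates to a tiling makes "not enough eligible
placements" a decidable error instead of a rejection-sampling stall; the
cost is that fields can only sit at grid phases, which is immaterial for
count statistics. Spot-in-field membership is half-open ([r0, r0+h) ×
[c0, c0+w)), so tiled fields partition spots exactly.

Two summaries are reported per region and are *not* interchangeable: the
pooled percentage 100·m/(m+w) over all fields (a count ratio, recomputable
exactly from stored counts) and the mean of per-field percentages (fields
with zero informative spots are dropped from the mean, with a logged
count). Printed percentages round half-up at the reported precision
(decimal arithmetic, not binary-float `round`).

Each area's per-field percentages are compared with the control region's by
an unpaired two-sided Student t test (equal-variance pooled estimate;
Welch behind a flag). The star legend is deliberately three-level —
"" (p ≥ 0.05), "*" (p < 0.05), "***" (p < 0.001), "****" (p < 0.0001) —
with no two-star tier. Degenerate zero-variance inputs return t = 0, p = 1
when the groups are identical.

## NGS heterogeneity profiles

Variant calls are kept iff the VAF exceeds 5 % (strict) in at least one
area and the matched-normal VAF is ≤ 2 %; the 2 % floor operationalizes
"absent in normal" against amplicon sequencing noise. Kept profiles are
divided by their across-area mean, making the output mean exactly 1 and the
profile invariant to any common per-sample scale such as tumor-cell
content. Heterogeneity is scored as max |normalized − 1| with a
configurable flag threshold (default 0.5). The flag is advisory: amplicon
NGS can manufacture apparent heterogeneity (PCR efficiency, homopolymer
errors), so a flagged variant is labeled a candidate requiring orthogonal
confirmation, never a verdict. The 0.5 default is an exposed guess — no
quantitative rule separates heterogeneous from homogeneous tumors in the
assay this models.

## Reproducibility and numerics

One global pipeline seed fans out to per-stage seeds via SHA-256 of
`"{seed}:{stage}"` (taken mod 2³¹), giving end-to-end determinism with
stage-level independence. Identical config + seed reproduces images,
tables and manifests byte for byte. Raw intensities flow unmodified from
simulation through detection — any brightness/contrast adjustment is
display-only by construction, since no rescaling code exists in the
quantitative path.

Problem sizes used by the test suite: the parameter-recovery experiment
runs the full pipeline on the preset for 20 seeds (~300 informative spots
per area each) and checks that per-area mean estimates sit within one
binomial standard error of the realized ground truth and that the
configured area ordering (1 ≈ 2 < 3 < 4) is recovered in ≥ 19/20 seeds;
artifact-exclusion rates are pooled over the same runs (~400 unspecific
events). The detector-equivalence check scans 200 random images up to
64×64, mixing float noise, plateau-rich small-integer images and blob
scenes.

## Known limitations

- No sub-pixel localization or spot-shape scoring; crowded fields merge.
- Artifact exclusion is geometric coincidence only; a bleed-through model
  with intensity arbitration is out of scope.
- The windowed-median background under-tracks sharp autofluorescence edges
  narrower than the window.
- Field selection on a tiling grid cannot express partially overlapping
  manual field choices.
- The heterogeneity flag threshold is a convention, not an inference.
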