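# rcaspot

Spot calling and spatial mutant-allele-frequency quantification for
padlock-probe / rolling-circle in situ mutation assays.

## The problem

Padlock probes ligated on cDNA and amplified by rolling-circle amplification
(RCA) turn single mRNA transcripts into diffraction-limited fluorescent
spots — rolling-circle products (RCPs) — whose detection-probe fluorophore
encodes the allele: one channel reports wild-type transcripts, another the
patient-specific mutant. Counting both classes of spots across several
dissected areas of a tumor section gives a *spatial* map of the mutant
allele frequency,

&nbsp;&nbsp;&nbsp;&nbsp;f̂ = m / (m + w),

where m and w are mutant and wild-type spot counts in a region — the in situ
counterpart of a sequencing variant allele frequency (VAF), and a direct way
to confirm or refute apparent multi-region heterogeneity seen in
amplicon-based NGS.

`rcaspot` implements the analysis side of such an assay as a tested,
seed-reproducible pipeline:

- **synthetic** — a tissue-image simulator: sparse Gaussian RCP spots on an
  autofluorescent background with Poisson noise, per-region spot densities
  and mutant fractions, an optional sub-clonal patch, and a configurable
  rate of "unspecific" artifacts rendered into two channels at once. Ground
  truth (every spot's position, class, region) is recorded, so each
  downstream stage is testable without microscope data.
- **imaging** — TIFF I/O, maximum-intensity projection of z-stacks, and a
  windowed-median local background map.
- **detection** — candidate spots as local maxima of a lightly smoothed
  projection; a spot is kept iff its raw peak / local background ratio
  exceeds a strict threshold (2 for quantification, 5 for overviews).
- **classification** — spots coincident across different non-nuclear
  channels (within 2 px) are flagged unspecific and excluded from counting;
  surviving spots inherit their channel's allele class; a color-coded
  overview rendering (wild-type green, mutant red) is available.
- **quantification** — ten non-overlapping fields of view per region, each
  with > 80 % tumor content; pooled percentage 100·m/(m+w), per-field
  percentages and their mean, and an unpaired two-sided Student t test of
  each area against non-neoplastic control tissue with a three-level star
  legend (\* p < 0.05, \*\*\* p < 0.001, \*\*\*\* p < 0.0001).
- **ngs** — multi-region VAF tables: keep calls with VAF > 5 % in at least
  one area and ≤ 2 % in matched normal, divide each kept profile by its
  across-area mean (mean set to 1), and score heterogeneity as
  max |normalized − 1| (flags are candidates that require orthogonal
  confirmation).
- **pipeline / CLI** — `rcaspot simulate | detect | classify | quantify |
  ngs-het | run` orchestrate the stages with one global seed.

## Worked example

Simulate a four-area tumor with mutant fractions 1 % / 1 % / 6 % / 14 %, a
sub-clonal 7 % patch in area 2 and a control region at the 1.5 % assay
background, then run the whole pipeline:

```python
from rcaspot.pipeline import PipelineConfig, run_pipeline
from rcaspot.synthetic import k386_like_preset

cfg = PipelineConfig(sim=k386_like_preset(), control_region=5,
                     field_size=(256, 256), seed=7)
res = run_pipeline(cfg)
for q in res.quant:
    label = "control" if q.is_control else f"area {q.region}"
    print(f"{label}: {q.pooled_pct:.1f}% ({q.mutant}/{q.total} signals; "
          f"Mean {q.mean_field_pct:.1f}%) {q.stars or ''}")
```

prints

```
area 1: 0.6% (2/312 signals; Mean 0.8%)
area 2: 2.4% (7/296 signals; Mean 2.2%)
area 3: 4.1% (13/314 signals; Mean 4.0%)
area 4: 12.9% (36/279 signals; Mean 12.4%) ***
control: 2.2% (6/273 signals; Mean 2.2%)
```

Each line is one tumor area: the pooled mutant percentage with its raw
counts, the mean of the ten per-field percentages (a different statistic —
both are reported), and the significance of the t test against the control
region. Area 2 sits above its configured 1 % because the sub-clonal patch
lies inside it; quantified alone the patch reads ≈ 7 %. The realized
ground-truth fractions for this seed are 0.6 / 2.3 / 4.4 / 13.1 / 2.1 % —
the pipeline recovers them within counting error.

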