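# Methods

This note documents the models, numerical choices, and known limitations of
the telopull pipeline, and what its synthetic-data generators do and do not
emulate.

## Label-free enrichment model

Protein-group tables are filtered by the three MaxQuant quality flags
(contaminant, reverse, only-identified-by-site) before any statistics; the
filter acts on rows only, so its order relative to column subsetting is
immaterial. Quantification columns treat both empty cells and literal 0 as
missing (MaxQuant writes 0 for unquantified proteins); this is configurable
at read time.

**Imputation.** Missing LFQ values in affinity enrichment are predominantly
missing-not-at-random: absence from the control pulldown usually means the
protein fell below detection there. Missing cells are therefore drawn from
a narrow band at the lower end of the observed distribution:
`L + (U − L)·X` with `X ~ Beta(a, b)`, defaults `a = b = 2`, where `L` and
`U` are the 0.2 % and 2.5 % quantiles of the pooled observed log2
intensities. Beta(2, 2) gives a bounded, unimodal draw centered in the
band; the band quantiles, shape parameters, and a per-column variant
(quantiles estimated per sample rather than pooled) are exposed in
`ImputationParams`. Pooled estimation is the default because per-column
tails are noisy at typical replicate counts. Draws are seeded; the imputed
cell mask is retained and the per-protein imputation counts are reported.
At least 20 observed values are required to estimate the band.

**Testing and calling.** Welch's *t*-test is computed from the closed-form
statistic and Welch–Satterthwaite degrees of freedom, with the two-sided
tail from `scipy.stats.t`. Degenerate inputs: two identical constant groups
return t = 0, p = 1; two constant but unequal groups have a zero standard
error, and the implementation returns t = ±inf with p equal to the smallest
positive float (a documented sentinel meaning "below machine precision")
and df = n_a + n_b − 2. Enrichment requires jointly exceeding the fold gate
and the p gate; inequalities are strict by default ("more than 4-fold"), so
boundary values are not called. The gate is applied symmetrically on the
control side with the negated log2 fold change. Raw Welch p-values are used
for calling, matching the screen design where the fold gate supplies
conservatism; Benjamini–Hochberg values are emitted alongside but never
used. Output is sorted by (p, −|log2 FC|, protein id) for byte-stable
reruns.

## Dimethyl-labeling arm

Stored ratios are assumed normalized upstream and follow the medium/light
convention; the sample sheet records, per ratio column, the crossover set
(forward/reverse) and which channel carried the bait, from which the ratio
is re-oriented to bait/control and log2-transformed (several columns per
set are averaged in log space). An optional per-set median-centering step
exists but is off by default. The concordance call requires both oriented
ratios to exceed the threshold on the linear-ratio scale (threshold 4 means
log2 ratio > 2), making single-set outliers uncallable; proteins quantified
in only one set are reported but never called. The label-incorporation gate
(labeled-peptide fraction ≥ 0.95, inclusive) consumes an upstream
peptide-level number and aborts the analysis unless forced.

## qFISH quantification

The analysis mirrors the ImageJ 3D Objects Counter workflow. Otsu's
threshold is computed per stack over 256 equal-width bins spanning the
observed range; the returned value is the smallest bin edge maximizing
between-class variance, with class means computed from the actual voxel
values (not bin centers), so the result is exactly reproducible by an
exhaustive search over candidate edges. Foreground is strictly above the
threshold. Connected components use 26-connectivity by default (6 and 18
available); objects smaller than 2 voxels are discarded; volume, mean gray
value, and integrated density are computed from the original intensities
inside each component. Per-image summaries default to the mean integrated
density per focus ("total per image" is also emitted), images with zero
foci are excluded with a warning, and strain means are scaled to the
wild-type mean, which maps to exactly 1. Thresholds are deliberately not
harmonized across stacks, reflecting acquisition with matched laser
settings. The DAPI channel is ignored; analysis is single-channel.

**Known bias.** The integrated density of a focus includes the background
pedestal under its above-threshold voxels. The pedestal is a larger
fraction of a dim focus than of a bright one, so relative-length estimates
are compressed toward 1 as background grows relative to focus amplitude
(e.g., a 1.6× strain reads ≈ 1.4 in the simulated example). The estimate is
invariant under a global intensity rescaling applied to all strains jointly,
but not under background changes.

## Orthology and synteny

Best hits are selected per query by minimum E-value, ties broken by maximum
bitscore then lexicographic subject id; a pair is orthologous when the two
best hits are mutual and both E-values are strictly below 1e-15. BLAST
execution is out of scope — the module consumes tabular (outfmt 6) files.
Synteny windows are coordinate-based (13 genes per side by default,
truncated at scaffold ends), not strand-aware, matching how neighbor lists
are retrieved from annotation marts. The default verdict mode, `any_side`,
accepts one conserved neighbor anywhere in the window; `both_sides`
requires support on each flank and is the stricter published reading of
"linkage in at least one of the neighboring genes upstream and downstream".
Both modes are computed by the toy-genome acceptance checks. Pairwise
identity uses a global alignment with BLOSUM62 and gap open/extend 10/0.5
(DNA: match 5, mismatch −4), and divides identical columns by the full
alignment length including gap columns, reported to one decimal.

## Synthetic-data generators

All generators are pure functions of (parameters, seed).

**Pulldown tables.** Latent per-protein log2 abundances are normal
(mean 25, sd 2 — typical MaxQuant LFQ magnitudes); spiked binders get a
+4 log2 shift (16-fold) in bait columns; per-cell replicate noise is
normal with sd 0.5; cells drop to missing with probability
`sigmoid(slope·(midpoint − latent))`, midpoint 22, steepness 1.5, giving
~8–10 % overall missingness concentrated at low abundance — the
left-censoring the imputation assumes. Decoy contaminant/reverse rows are
appended at 2 % each. Defaults use 4 replicates per condition so that power
properties are informative at the screen's thresholds. What is *not*
emulated: correlated replicate structure (batch effects), peptide-level
variation, ratio compression, and abundance-dependent variance; passing
recovery tests here shows the calling machinery is correct and calibrated
under MNAR dropout, not that any real experiment has ≥ 90 % recall.

**DML tables.** One ratio column per crossover set; spiked proteins carry
the 16-fold bait/control ratio in both sets, nulls are log-normal around 1
(sd 0.3 log2 in the concordance checks). Stored ratios follow the
medium/light convention with the label switch, so orientation logic is
exercised. Per-set missingness is independent Bernoulli at 3 % — ratio
columns carry no per-sample intensity on which to condition dropout, and
abundant bait-enriched proteins are nearly always quantified in both sets.

**FISH stacks.** Foci are 3D Gaussians (sd 1.2 voxels axially, 2 laterally)
with log-normal amplitude variation, placed fully inside a 16×64×64 stack
on a constant background of 5 with Gaussian read noise (sd 2); the
per-strain amplitude scale factor is the ground-truth relative telomere
length. The high signal-to-background ratio (peak 400 vs background 5)
represents a bright PNA probe imaged with per-sample-adjusted laser
settings; at lower SNR the pedestal bias above dominates. Optics (PSF,
z-anisotropy beyond the Gaussian sd), nucleus structure, and focus overlap
crowding are not modeled.

**Genome pairs.** Gene order is initially identical across species;
a configurable fraction of genes has a one-to-one ortholog; relocations
move single ortholog genes to fresh scaffolds, breaking their local synteny
by construction while leaving neighbors' verdicts intact. True pairs
receive mutual hits with E-values below 1e-20, decoys above 1e-10, so the
1e-15 gate separates them with margin. The ground-truth verdicts are
derived from positional counting at construction time, independent of the
synteny caller.

## Problem sizes

The calibration and recovery checks use 50 simulations of 2000 proteins
(LFQ and DML), 100 random stacks for the Otsu oracle, 3 simulations × 10
images per strain for the qFISH recovery, and 50 toy genome pairs of 3×40
genes — sizes at which the measured fractions are stable to well within
the tolerances they are compared against.

## Limitations

- The enrichment analysis assumes intensities are normalized across runs
  upstream (as LFQ provides); no within-pipeline normalization is applied.
- Imputation treats all missingness as left-censored; values missing for
  technical reasons at high abundance are imputed too low.
- The qFISH stage quantifies total probe signal per focus; it does not
  assign foci to chromosome ends or separate adjacent telomeres closer
  than the object-counter resolution.
- Synteny verdicts depend on the annotation's gene set: unannotated or
  mispredicted neighbors reduce conserved-neighbor counts.
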