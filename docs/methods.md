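# Methods

This note documents the models and procedures behind `aeroferm`, the
parameters that matter, the design choices made where more than one
reasonable option existed, and what the synthetic benchmarks do and do not
demonstrate.

## Extracellular acidification rate (ECAR)

A fermenting yeast culture in weakly buffered medium acidifies its
surroundings; with phenol red as indicator, the absorbance at 560 nm tracks
pH.  The pipeline models the standard curve as affine, pH = a·A560 + b,
fitted by ordinary least squares **with pH as the response**, so that
downstream conversion never divides by a fitted slope.  The calibration range
(observed absorbance extremes) is carried on the curve; conversions outside
it are flagged per timepoint as extrapolation but never clipped, since there
is no physical justification for clipping an indicator reading.

Each well's acidification rate is the OLS slope of pH against time,
converted from the input's minutes to pH/h.  By default the slope is fitted
over the full measurement window (31 reads over 90 min in the emulated
design); a `[t_start, t_end]` sub-window is available but not the default,
because the full-window fit is the simplest defensible estimator and is
affine-equivariant (tested).  Non-finite readings are dropped pairwise; a
well with fewer than three usable timepoints is an error.

ECAR is the paired difference: slope of the carbon (2% dextrose) well minus
the slope of the same replicate's water-control well.  Pairing is by
(strain, replicate); unpaired wells are reported and skipped rather than
silently matched across replicates.  Differencing per-pair (rather than
between condition means) preserves the day-to-day blocking of biological
replicates and cancels any drift shared by the paired wells (tested
numerically).  Species are summarized as mean, sample SD and n over
replicate ECARs; negative values mean acidification, and the rapid-fermenter
regime in this study design sits near −0.03 pH/h.

## Phylogenetic comparative analysis

Species are not independent samples: a trait evolving by Brownian motion on
a rooted tree with branch lengths has tip covariance `C`, where `C[i,j]` is
the depth of the most recent common ancestor of tips *i* and *j* and the
diagonal holds root-to-tip distances.  `bm_covariance` builds this in one
postorder pass; it is symmetric and positive semidefinite by construction
(property-tested on random trees).

PGLS fits `y = β₀ + β₁x + ε`, `ε ~ N(0, σ²C_λ)` where Pagel's λ multiplies
the off-diagonal of `C` (λ=0: star phylogeny, equivalent to weighted OLS;
λ=1: pure Brownian motion).  The solver uses a Cholesky factorization of
`C_λ` — never an explicit inverse — and reports β, its standard error,
t = β/se with n−2 degrees of freedom, a two-sided p-value, and a signed
correlation `sign(β)·√R²` where R² is measured against the intercept-only
GLS fit under the same covariance.  A singular `C_λ` (e.g. duplicated
zero-length tips) is an error; no jitter is added silently.  The default is
fixed λ=1, the common default of the comparative-methods literature and
exactly reproducible; `lambda="ml"` profiles the exact multivariate-normal
likelihood (σ² profiled out) on a 0.01 grid with bounded refinement.

Per-family tables regress the trait on each gene family's copy number and on
the row-sum `total` column; the trait is the response and copy number the
predictor (the direction is a documented choice — the hypothesis is that
copy number predicts glycolytic rate).  Pearson correlations with the figure
convention significance stars (\*p<0.05, \*\*p<0.01, \*\*\*p<0.005) are
produced alongside, with no multiple-testing correction applied to the
starred values (matching the presentation convention) but a
Benjamini–Hochberg column emitted for users.  Families with zero copy-number
variance yield missing correlations, never r = 0.  Species names are matched
across tree, trait and count tables case-insensitively with underscore/space
folding; unmatched names are logged and dropped, and the tree is pruned to
the overlap with unary nodes collapsed (patristic distances preserved,
tested against a distance-matrix oracle).

## Orthogroup expression

Cross-species expression is compared at the orthogroup level: per sample,
counts of the species' member genes are summed; per species, member gene
lengths are summed ("sum of counts and gene lengths").  TPM is computed from
the summed quantities: rate = count/length, scaled so each sample's rates
total 10⁶.  Orthogroups absent from a species (no member genes) are excluded
from that species' normalization — they have no defined length — rather than
given a pseudo-length.  Gene length defaults to the annotated gene span
(end−start+1, GFF3 1-based inclusive); an exon-union option exists because
the original length source is not stated.  Counts are taken as given
(HTSeq-style two-column files, `__*` summary rows dropped and logged);
fractional counts, which arise from fraction-of-multimapper counting, are
accepted as nonnegative reals with a warning.  No TMM or effective-library
normalization is applied: the comparison is on plain TPM.

Between-species significance is a Welch two-sided t-test on log2(TPM+1)
replicate values against the reference species, the test family used
elsewhere in this kind of assay work; the exact test behind the original
figure annotations is not stated, so this is a documented assumption.  The
effect size is log2((mean_other+1)/(mean_ref+1)) — finite at zero and
exactly 0 for identical groups.  Both-constant groups are special-cased
(p=1 when equal, p=0 otherwise) since the Welch statistic is 0/0 there.
BH-adjusted p-values are added per species.

## Promoter motif scanning

A putative promoter is the flat 1 kb window immediately upstream of the
coding sequence, strand-aware, truncated (and flagged) at contig edges, and
deliberately not trimmed for overlapping upstream genes.  The anchor feature
is configurable (CDS by default; CDS segments are grouped by parent gene and
reduced to their span).  Coordinates are GFF3 1-based inclusive at the
interface and 0-based half-open internally.

Motifs are IUPAC degenerate consensi with run-length shorthand
(`CGGN{11}CCG` = 17 positions).  Scanning reports every (possibly
overlapping) offset where each base is in the motif's allowed set; genomic
`N` never matches (conservative).  The default Gal4p consensus is its own
reverse complement — asserted at runtime — so forward-only scanning sees
every genomic site; `strands="both"` exists for non-palindromic motifs and
de-duplicates offsets describing the same genomic window.  Family summaries
take, per species and family, the maximum count over member orthologs ("the
ortholog with the highest number of binding sites").

Site ablation mutates only the motif's non-degenerate positions (the
CGG/CCG triplets), one seeded deterministic edit per site per round,
re-scanning both strands until zero matches remain anywhere (≤10 rounds,
else an error); on random promoters this converges with ≈1 edit per site.

## Synthetic data

The generators define the study conditions and write a `truth.json` next to
their outputs so recovery can be scored without re-simulation.  One root
seed yields an independent substream per generator
(`default_rng([seed, key])` with fixed keys), so outputs are byte-stable
under identical configurations and adding a generator never perturbs the
others.

- **Plate**: linear pH trajectories inverted through a standard curve of
  slope 1.0 pH per absorbance unit (intercept 6.0; pH 6.5–7.5 spans A560
  0.5–1.5 — the real indicator curve is not printed, and this response makes
  the stated absorbance noise of 0.005 sd correspond to 0.005 sd in pH);
  Gaussian read noise; calibration-table noise separate and 0 by default.
  Defaults: one rapid strain with true ECAR −0.032 pH/h, 3 replicates,
  31 timepoints / 90 min.
- **Tree/trait/counts**: pure-birth tree (unit rate) scaled to depth 1 so
  σ² is the trait variance at the tips; per-family copy numbers Poisson
  with the mean shifted +2 inside one random clade per family, giving the
  predictor phylogenetic signal (this is what makes the PGLS-vs-OLS
  contrast visible); trait = β·total + N(0, σ²C), defaults β = −0.001 pH/h
  per copy, σ² = 10⁻⁴, 32 taxa, 13 families.  The two root clades are
  exported as taxonomic "orders" for subset analyses.
- **Expression**: four species in two phenotype groups, four replicates
  each, 200 orthogroups with 1–3 member genes per species (lengths uniform
  500–5000 bp), negative-binomial counts (dispersion 0.1) whose per-gene
  mean is orthogroup abundance × length/1000 — reads scale with transcript
  length and every copy is expressed at the orthogroup's level, so
  Σcount/Σlength is an unbiased abundance estimator.  Ten orthogroups carry
  a 4× fold change in the low-ECAR group.
- **Genome**: uniform-background contigs, genes alternating strands with
  >1 kb spacing, a configured number of non-overlapping consensus instances
  implanted at recorded promoter offsets; the G-free background option
  removes C from the promoter alphabet of either strand's windows so
  spurious sites are impossible and counts equal implants exactly.

### What the benchmarks do not show

The simulations validate estimator correctness and calibration, not
biological realism: plate trajectories are exactly linear (no lag or
saturation phase, no evaporation drift); the Brownian model is the same one
PGLS assumes, so these tests cannot detect model misspecification on real
traits; expression counts have no batch structure, GC effects or
library-composition bias; genome backgrounds are uniform random, unlike real
intergenic composition.  Agreement with the naive scanning and
normal-equation oracles is exact, but concordance with the original web-tool
site counts on real genomes is only expected for exact-consensus matching.

## Problem sizes and numerical choices

Monte-Carlo checks use: 100 16-taxon trees for GLS-oracle agreement (1e−8),
400 replicates on 128-tip trees for null calibration (5% ± 2.5%), 200 for
95% CI coverage (±4%), 800 for estimator bias (bound 10% of the empirical
SE ≈ 2.8 MC σ), 1000 random 1-kb sequences for scanner/oracle identity, and
50 mini-genomes for extraction/mirror identity.  These sizes make each check
statistically meaningful at interactive runtimes.  Linear solves use
`scipy` Cholesky factorizations; OLS fits use closed-form `polyfit`; TPM
conservation is asserted to 10⁻⁶ relative; slope/curve oracle agreement to
10⁻¹⁰ (closed-form least squares on well-conditioned inputs).

## Known limitations

- λ is the only covariance modifier implemented (no OU/κ/δ models), and
  PGLS is simple (one predictor) by design.
- TPM-level Welch tests ignore count-level mean–variance structure; for
  real differential-expression inference a negative-binomial model with
  dispersion shrinkage would be preferable (explicitly out of scope).
- Promoter extraction trusts the annotation's coding-sequence start;
  misannotated starts shift windows.
- Ablation minimizes edits greedily; it does not prove a global minimum
  edit set (adequate for reporter-construct design, the intended use).
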