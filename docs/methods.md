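# Methods

## The protection assay as a generative model

The package models an extracellular RNA preparation (the particle pellet of
apoplastic wash fluid) as a population of RNA *species*. Each species has a
source locus on a toy genome, a length (10–600 nt), a circularity flag, a
relative molar abundance, and a triple of compartment fractions summing to 1:

* `inside_EV` — enclosed in extracellular vesicles; inaccessible to protease
  and RNase unless the membrane is disrupted;
* `outside_protected` — outside vesicles, bound by RNA-binding proteins;
  resistant to RNase A while the protein is intact;
* `outside_naked` — free RNA.

Protein protection comes in two modes. `full` protection shields the whole
molecule (the miRNA/tasiRNA case: their length distribution is unchanged by
RNase A alone). `footprint` protection shields only the protein-bound window:
RNase A trims a 31-nt Pol IV precursor down to a 16–17 nt footprint. The
footprint operator replaces the fragment by the uniform mixture over footprint
lengths (16 and 17, equally weighted) and start offsets within the parent.

Treatments are deterministic operators on expected fragment weights:

| treatment | effect |
|-----------|--------|
| C (buffer) | identity |
| R (RNase A) | removes `outside_naked`; footprints footprint-mode `outside_protected`; spares full-mode protected and `inside_EV` |
| TR (trypsin + RNase A) | removes everything outside vesicles |
| RR (RNase R) | removes linear fragments up to an escape probability (default 0.02); spares circles |

Working on expected weights (the infinite-molecule limit) rather than on
individual molecules makes every treatment exactly reproducible and pushes all
stochasticity into sequencing, where it belongs statistically; the per-molecule
view is recovered when reads are drawn.

## Replicate and sequencing noise

Each biological replicate represents one harvest of the extracellular pool.
Species abundances in replicate *r* are the population weights times a Gamma
multiplier with mean 1 and variance `overdispersion` (default 0.05) — the
gamma–Poisson construction of a negative binomial. Crucially, the multiplier
is a property of the *replicate*, not of the treatment: in the assay design
the three treatments are applied to aliquots of the same pellet, so C1, R1 and
TR1 share replicate 1's multipliers, while the downstream test still analyses
the groups as unpaired (as the standard count-based workflow does). Sequencing
then draws a fixed `depth` of reads per library (default 10⁶) from the treated,
perturbed fragment weights — multinomially, hence independently per library.
Reads are exact fragment subsequences truncated at the length cap (34 nt for
small-RNA presets, 50 nt for the RNase R preset) with constant quality.

What the generator deliberately does not emulate: sequencing errors, adapters,
ligation and GC biases, quality-score structure, RNA secondary structure,
partial digestion, vesicle subpopulations, or genotype effects. Green tests
therefore demonstrate that the *inference machinery* is correct under its
stated model, not that the model captures every property of real libraries.

## Presets

`default` — 5 × 50 kb chromosomes, ~340 species in 11 origin categories.
Class weights put the control library's top length classes at 21 > 22 > 31 nt,
with ≥15% relative margins so the ranking survives replicate noise. The 31-nt
class is 93% footprint-protected, so RNase A alone produces twin 16/17-nt
modes; trypsin + RNase A leaves the vesicle-enclosed tiny-RNA (10–17 nt)
classes, weighted so 10 nt > 12 nt > the rest. Every category hosts tiny-RNA
species, and six circRNA loci are annotated.

`fig4` — 427 miRNA loci. 94 carry equal high weights; 333 carry ~10⁻⁷ relative
weight (expected count ≈ 10⁻³ at depth 10⁶, so the >1 RPM filter retains
exactly the 94 with probability ≈ 1). The 94 split into clades by compartment
fractions; with full protection, survival under (C, R, TR) is
(1, in+prot, in):

| n | fractions (in, prot, naked) | planted call |
|---|------------------------------|--------------|
| 7 | (0.20, 0.00, 0.80) | inside_EV |
| 7 | (0.25, 0.75, 0.00) | inside_and_outside_protected (TR≈R) |
| 3 | (0.60, 0.40, 0.00) | inside_and_outside_protected (TR>R) |
| 14 | (0.022, 0.978, 0.00) | outside_protected |
| 10 | (0.004, 0.996, 0.00) | outside_protected |
| 14 | (0.025, 0.000, 0.975) | outside_unprotected |
| 7 | (0.004, 0.026, 0.970) | outside_unprotected |
| 32 | (0.05, 0.15, 0.80) | none (non-differential) |

All planted effects are ≥2.5-fold against the non-differential class (Wald
|z| ≥ 4.5 at depth 10⁶), so detection power is ≈1. The sub-clade fractions are
balanced so that, in each treatment column, the median of the DESeq2-style
count ratios falls inside the non-differential block — 31 features firmly
below and 31 above in the C and TR columns. In the R column the imbalance
(28/34) is unavoidable: every protein-protected feature must rank above the
null class after RNase A. Anchoring the median this way is what makes
"direction relative to normalization" equal "direction relative to the
planted null", i.e. what lets a known truth be planted at all.

`fig4-tas` — same construction with 1581 tasiRNA loci, 27 planted above the
5-RPM filter (16 protein-protected, 11 naked; none vesicle-enclosed, matching
the observation that no tasiRNA shows the inside-EV pattern).

`rnaser` — six circles of 60–76 nt carrying 60% of the molar weight plus
twenty 120-nt linear species. Circles shed read-length windows at every
rotational offset (wrapping), so with 50-nt reads and ≥10 nt overlap required
on each side, 31/L of each circle's reads are detectable junction reads —
≈45% of the library after RNase R (2% linear escape), versus ≈27% untreated.
Junction cores are checked against the linear genome at generation time so
the detector's specificity is measurable.

Preset depths and read lengths are study conditions, recorded in
`presets.PRESET_DEFAULTS`; the seed changes the genome sequence but not the
planted structure.

## Quantification

Reads are error-free genome substrings, so mapping is exact full-length
matching seeded by a k-mer index (k = 10, the minimum insert size; both
strands). A multimapping read is counted once, under the highest-priority
category among its hits — rRNA > tRNA > snRNA > snoRNA > miRNA > TAS > polIV
> TE > mRNA > circRNA > intergenic — so structural classes absorb ambiguous
reads rather than inflating regulatory ones. Reads inside protein-coding
genes take the sub-feature (5′-UTR / CDS / intron / 3′-UTR) with the largest
overlap, ties to CDS, and are counted against the parent gene. Hits on either
strand count toward a feature regardless of the feature's strand. RPM uses
mapped reads only as the denominator; identical read sequences are mapped
once and cached.

## Differential accumulation

A deliberately small re-implementation of the standard NB workflow:
median-of-ratios size factors (features with any zero excluded from the
median; an optional positive-count fallback exists but is off by default);
per-feature method-of-moments dispersion α̂ = max(0, (var − mean)/mean²)
computed on normalized counts *within* treatment groups and pooled by degrees
of freedom — pooling across groups would absorb real treatment effects into
the dispersion — then averaged (weight 0.5, configurable) with a fitted trend
α_tr(μ) = a₀ + a₁/μ and floored at 10⁻⁸. The Wald statistic uses group means
of normalized counts floored at 0.5 (to avoid infinite fold changes), the
delta-method SE from μ + αμ², two-sided normal p-values, and
Benjamini–Hochberg step-up correction with NA p-values excluded from the test
count. No outlier refitting, independent filtering, or fold-change shrinkage:
the localization logic consumes only sign and significance. On null
simulations (500 features, dispersion 0.1, 3 vs 3) the BH-significant
fraction at 0.05 stays below 0.05.

## Localization calls

Per feature, each contrast (R_vs_C, TR_vs_C, TR_vs_R) is reduced to
up/down/ns at BH-adjusted p ≤ α (default 0.05), and the triple is mapped
through a total decision table over all 27 patterns (see README). Two merges
are deliberate: the two protein-protected clades collapse into one
`outside_protected` call and the two unprotected clades into
`outside_unprotected`, since they differ only in magnitude, not
interpretation; and (up, up, up) joins (up, up, ns) as
`inside_and_outside_protected`, the TR-vs-R surplus marking a larger
vesicle-internal share. Category-level profiles compare mean category shares
between treatments with a relative-change threshold τ (default 20%): share up
in R and down in TR→R is protein protection; the opposite movement is the
tRNA-like mixture of naked and vesicle RNA; up in TR vs C is vesicle
enrichment; otherwise stable.

## circRNA quantification

For each annotated circle, the junction sequence is the last F bases followed
by the first F bases of the circle on its annotated strand (F = read length
by default, so any junction-spanning read is contained). A read is a junction
read iff it (or its reverse complement) occurs in a junction sequence
straddling the midpoint with ≥ m bases on each side (m = 10; "concordant")
and has no exact full-length match in the linear genome ("exclusive" —
paired-end concordance collapses to single-end containment because synthetic
reads are single-end). The per-library report is 100 × junction reads / total
reads. Increasing m can only decrease the count; on linear-only pools the
count is zero by construction.

## Numerical and design choices

* Coordinates are 0-based half-open internally, 1-based inclusive in GFF3.
* All randomness derives from one master seed through stable named streams
  (`child_rng(seed, stage, ...)`), so any stage can be rerun standalone with
  identical results; the pipeline manifest records per-stage file hashes.
* Degenerate inputs: zero depth yields empty libraries and a quantify-stage
  abort; empty pools with positive depth, unknown presets/treatments,
  single-replicate dispersion estimation, flank longer than a circle, and
  negative RPM thresholds all raise typed errors.
* Problem sizes: presets run at their documented depths (10⁶ small-RNA reads,
  10⁵ RNase R reads) per library; the full reproduction script completes in
  well under a minute on one CPU because read multisets are aggregated by
  sequence.

## Known limitations

* Exact matching cannot represent sequencing errors or near-identical loci;
  the mapper is validated against a brute-force scan, not against aligner
  behaviour on real data.
* The Wald test is asymptotic; with three replicates its null is mildly
  heavy-tailed, which matters only near the significance boundary.
* Compartment fractions are preset choices, not estimates — the assay's
  absolute inside/outside partition per class is not identifiable from the
  published summaries, only the directional patterns are.
* Whether 31-nt Pol IV precursors extend 5′ or 3′ of their mature products is
  unspecified; the generator centres footprints uniformly within the parent.
* RNase efficiency differences between treatments (e.g. residual trypsin
  slightly inhibiting RNase A) are not modelled.
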