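# Methods

## Study design being modelled

The pipeline integrates two genome-wide readouts of a transcription
factor's activity in *Drosophila* eye/antennal imaginal discs: a
three-genotype expression array (control; factor overexpressed; factor
overexpressed in polarity-mutant, tumourigenic clones) in triplicate, and
ChIP-seq of the factor in the two overexpressing conditions against input
chromatin. Direct-target candidates are genes that are both deregulated
and bound; the six-class scheme further stratifies them by *where* they
are bound and *when* they are deregulated.

## Differential expression

Each non-control genotype is contrasted with control on the log2 scale:
log2FC is the difference of group means, and the p-value comes from a
two-sided two-sample t-test. The Welch (unequal-variance) form is the
default because with three replicates per group there is little power to
verify variance homogeneity; a pooled-variance option is exposed. The
original analyses of such arrays typically used a moderated linear-model
statistic; only the thresholds and the Benjamini–Hochberg adjustment are
treated as fixed contracts here, and BH is applied per contrast over all
probe sets jointly. A probe set is called deregulated when |log2FC| > 1
*and* adjusted p < 0.05, both strict, encoded +1/−1/0.

Degenerate zero-variance probes (which arise in noise-free simulation)
get p = 1 when group means agree and p = 0 with a warning when they
differ.

Gene reconciliation: a gene is deregulated in a contrast when any of its
probe sets is; it is assigned to *both* genotypes when a single probe set
is deregulated in both. When distinct probe sets are deregulated in
different single genotypes (a case the class scheme does not address),
union semantics assigns *both* and sets a `mixed_evidence` flag. A
`conflict` flag per contrast marks genes carrying both up- and
downregulated probe sets, mimicking discordant-transcript genes.

## Peak calling

The caller is deliberately simple and fully specified, parameterised by
read extension length 40 bp, merge gap 40 bp, FDR cut 0.01 and p-value cut
10⁻⁴ (the working values for short-read ChIP of a sequence-specific
factor); it is not a reimplementation of any published two-pass
segmented-simulation algorithm, and precomputed peak BEDs can be supplied
instead. Stranded 5′ read positions are extended 3′-ward to 40 bp;
candidate segments are maximal runs of depth ≥ 2 (`seed_depth`, a required
but otherwise free seeding rule — configurable); segments separated by
≤ 40 bp merge. For each merged region with k_s sample reads and k_i input
reads overlapping it, the input is scaled by r = total sample reads /
total input reads and enrichment is tested as a sign test: p = upper tail
of Binomial(k_s + round(r·k_i), ½) at k_s. BH runs across regions; a
region is kept when p < 10⁻⁴ and q < 0.01. Read-count-ratio scaling was
chosen over regression-slope scaling for determinism on synthetic
backgrounds (a slope option would be the first extension for real data
with non-uniform input). Peak *height* is the maximum per-base extended
depth in the region; "top peaks" selection uses height ≥ 40, inclusive.

The symmetric null (sample ≡ input) cannot produce p < 10⁻⁴ because k_s
is then about half of the binomial count. Conversely the caller retains
occasional background regions at the configured FDR — roughly one per
simulated genome — which is expected behaviour, not an error.

## Peak-to-gene assignment

Coordinates are 0-based half-open internally; BED is read natively, GFF3
converted from 1-based inclusive on input. Promoters are per-transcript:
[TSS−500, TSS) on the + strand and the mirrored window on the − strand,
clipped at chromosome bounds and deduplicated; introns are the gaps
between consecutive exons. A gene is flagged for a condition when ≥ 1 bp
of any significant peak overlaps any promoter or intron of any of its
transcripts (the weakest reading of "within"; a midpoint-containment mode
is available). One peak may flag several genes. Overlap queries use an
interval tree; correctness is property-tested against a quadratic
all-pairs oracle.

## Class integration

ChIP target flags are first restricted to genes measured on the array.
Genes deregulated in the tumourigenic contrast (pattern *both* or
*tumour-only*) partition into classes: peaks in both conditions → 1
(dereg both) / 2 (tumour-only); peaks in the tumour condition only → 3 / 4
(same split); no peaks → 5; peaks only in the non-tumour condition → 6.
All other genes are reported with their patterns but unclassified
(label 0). "Associated with peaks" for the per-sample percentages means
having ≥ 1 significant peak in that sample's own peak set, and
percentages are rounded to integers. The hypergeometric set-enrichment
test is a generic one-sided tail with BH across terms; no ontology-graph
propagation is attempted.

## Motif rank-shift overrepresentation

PWMs are scored as log2 odds of pseudocount-regularised column
probabilities (pseudocount 0.5) against the background composition
(uniform by default). A window is a hit when its score reaches 0.8 × the
maximum achievable score — the scanning threshold of the original tool is
not documented, so this conventional fraction is the default and is
exposed. Both strands are scanned; N-containing windows are skipped. Hit
densities are (hits + 0.5) / total bp per sequence set (the pseudo-hit
avoids zero densities; the normalization the method names — "by total
size" — is stated without a formula, and density per bp is its simplest
realisation). Matrices are ranked by density within the peak set and
within the genome baseline separately (densest = 1, ties broken by matrix
id), and selected when rank_genome − rank_set ≥ 200 *and* the normalized
log2 fold change is positive — in every ChIP experiment when several are
supplied. The 200-position threshold is calibrated to an 827-matrix
collection; tests and the acceptance script scale it proportionally
(200/827 of the collection size). Two caveats are documented rather than
hidden: with unequal set lengths, zero-hit matrices get a positive fold
change from the pseudo-hit alone, and rank shifts on small collections
are granular, so selection on < ~50 matrices should be read as a smoke
signal only.

## qPCR arithmetic

Expression validation follows the 2^(−ΔΔCt) method: technical replicates
are averaged on the Ct scale; ΔCt = mean Ct(target) − mean Ct(normalizer)
per condition (normalizer CG6044 by default); ΔΔCt subtracts the
reference condition; fold = 2^(−ΔΔCt). Replicate-level folds pair
biological replicates by index. ChIP validation reports
2^(Ct_controlIP − Ct_antibodyIP), i.e. relative to a nonspecific-IgG
control assigned a level of 1 — the minimal formula consistent with that
baseline (percent-of-input is out of scope). Amplification efficiencies
are fixed at 2.

## Synthetic data: what it emulates and what it does not

The generator plants: per-gene deregulation directions with pattern
fractions both 12% / non-tumour-only 4% / tumour-only 6% (chosen to
mirror the probe-level Venn proportions of the study design modelled);
binding-site patterns both 15% / 4% / 5% likewise; effect size 2.0 log2
units with Gaussian noise sd 0.25 (the settings at which planted DE
recovery is assessed); 200 genes on 2 × 600 kb chromosomes — the smallest
genome that holds 200 three-exon genes without overlap and with
intergenic gaps > 1 kb, so neighbouring promoter windows never overlap
and each planted peak flags exactly one gene. Reads are 1 bp stranded 5′
anchors (extension is the caller's job): a uniform background at 0.02
reads/bp (mean extended coverage ≈ 0.8×) plus 120 reads flanking each
planted site (5′ ends 5–45 bp away), giving planted heights around 100,
comfortably above the 40-read top-peak cut. Multi-probe genes are 10% of
the universe, a third of the deregulated ones "conflicting" (second probe
set shifted oppositely). Baseline intensities are uniform in [6, 12] log2
units — typical array range; the value is immaterial to contrasts. An
optional `class_plan` plants exact per-class gene counts for end-to-end
identity checks.

Deliberately not modelled: sequencing error and duplicate reads,
mappability structure, fragment-size distributions (the ~500 bp fragment
length is carried in the config but reads are placed directly around
sites), probe chemistry and normalization artifacts, overlapping or
nested genes, distal enhancers. Passing tests therefore demonstrate the
*logic* of every stage and exact bookkeeping, not robustness to the
artefacts of real libraries.

Determinism: all randomness derives from `SimConfig.seed` through
per-stage spawned generators; identical configs give byte-identical
output files.

## Numerical and testing notes

- BH adjustment delegates to statsmodels and is property-tested against
  an exhaustive evaluation of the step-up definition (n ≤ 12).
- The caller's binomial example values in tests were frozen from exact
  tail enumeration (e.g. upper tail of Binomial(32, ½) at 30 =
  529/2³² ≈ 1.23 × 10⁻⁷).
- Planted-DE recovery bounds (sensitivity ≥ 0.75, FDP ≤ 0.05) were frozen
  from a 30-replicate Monte-Carlo at the identical generator settings;
  per-study sensitivity ranged 0.78–1.00 because a 4-df variance estimate
  occasionally inflates the adjusted p past 0.05 even at effect 2.0.
- Motif scanning is vectorised numpy; hit sets are property-tested
  against a brute-force both-strand window oracle and cross-checked
  against the Biopython PSSM scores. Palindromic motifs legitimately
  yield a + and a − hit on the same window.
- Problem sizes in tests and the acceptance script (200-gene studies,
  60-sequence motif sets, 25-matrix collections) are the package's chosen
  desk-scale working points; every quantity they feed is recomputed at
  run time.
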