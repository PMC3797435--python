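# Methods

## The model

`methylscape` treats MBD2 pull-down sequencing as a count-enrichment
problem. Tags (mapped read 5′ starts) from the enriched library are
compared window by window against a non-enriched input library under a
Poisson model: the input gives the expected local rate, and a region is
"methylated" when the enriched counts exceed that expectation beyond a raw
p-value cutoff of 10⁻¹⁰. Everything downstream — feature annotation, stage
signatures, fold-change clustering, repeat-class statistics, expression
integration, network characterization — consumes the resulting interval
sets and count matrices.

All genomic intervals are 0-based half-open internally and in BED output;
GTF output is 1-based closed. Strand handling: tags are unstranded for
calling (MBD2 capture has no strand); promoter/downstream windows are
strand-aware because TSS semantics force it.

## Peak calling

- Window size 100 bp; tags are counted by 5′ start; the last partial
  window is kept. No fragment-shift model is applied (capture fragments
  average ~250 bp; a shift option was considered and omitted because the
  simulator places tags uniformly within fragments' source intervals).
- Per-window expectation λ = max(local input rate × N_sample/N_input,
  λ_BG). The local input rate is the input count averaged over a centered
  5 kb span: a single 100 bp input window holds only ~1–2 tags, far too
  few to estimate a background, and using it raw roughly doubles the
  variance of λ and costs ~10 points of sensitivity. 5 kb is the scale at
  which the input is locally flat. λ_BG (floor) defaults to the sample's
  genome-wide mean window count and exists to prevent zero-expectation
  artifacts in input gaps.
- Two-level thresholding: windows significant at seed_p = 0.05 become
  candidates; candidates separated by ≤ merge_gap (100 bp) merge, interior
  gap windows included; the final cutoff (10⁻¹⁰) applies to the merged
  region's summed count against its summed expectation. A single window
  rarely carries enough tags to clear 10⁻¹⁰ on its own at realistic depth,
  so the decisive test is at region scale. The seed threshold only shapes
  candidate regions; with the final cutoff at 10⁻¹⁰, false regions are
  negligible (measured: 0 false peaks across 20 simulation seeds at ~80 000
  windows each).
- A greedy region-growing variant (absorbing adjacent above-expectation
  windows) was evaluated and rejected: it diluted region significance with
  background windows and lowered sensitivity.
- Technical replicates are pooled by tag concatenation before calling.
- Multiple testing: the raw 10⁻¹⁰ cutoff is used as-is for peaks (no FDR),
  matching standard practice for this assay; the enrichment modules that
  do need FDR use Benjamini–Hochberg.

## Feature assignment

Six genic categories plus intergenic. Category regions per gene: promoter
= 3 kb 5′ of the TSS; downstream = 3 kb 3′ of the TES (TES anchor chosen
over the stop codon so noncoding genes are handled uniformly); 5′/3′ UTRs
from the CDS extent; exon = CDS portions (all exons for noncoding
transcripts); introns between exons. These partition the extended gene
span, which a test asserts base by base. Assignment maximizes overlap
length over all (gene, category) pairs; exact-length ties (the overlap rule
is silent there) fall back to a fixed priority promoter > 5′UTR > exon >
3′UTR > intron > downstream, favoring the regulatory interpretation; the
order is pinned by test. Whether a TSS-spanning peak is promoter or 5′UTR
is therefore decided first by overlap length, then by that priority.

Transcript classification is coding iff (a) any exon overlaps a known
coding exon by ≥ 1 bp, or (b) the longest ORF exceeds 120 codons and its
nucleotide length exceeds one third of the transcript; a curated noncoding
override list (a lncRNA-registry stand-in) wins over both. External
coding-potential scores are out of scope; the classifier uses only the two
structural criteria plus the override.

## Cross-sample region identity

Two regions from different samples are "the same" when each covers ≥
min_frac (default 0.5) of the other (reciprocal overlap). This identity
underlies Venn membership counts (reported in units of union regions, with
the per-sample membership matrix also emitted, since per-sample peak counts
differ when peaks fragment), stage-specific core derivation (matched in all
core labels, unmatched in all excluded labels) and
demethylation-reversibility (present untreated, unmatched in treated).

## Quantification and clustering

Effective reads scale each line's counts by input_total/sample_total.
Fold change uses pseudocount 1 in numerator and denominator (the source
procedure is silent on zero-input regions); regions with zero counts in
every line are excluded beforehand. Row normalization uses the sample
(n−1) standard deviation — the population-sd alternative is computed in a
test to document the choice — and constant rows are dropped with a warning
rather than aborting a run. Clustering: distance 1 − Pearson between cell
lines, average linkage (UPGMA) by default with single/complete available;
the linkage choice is not dictated by the source method name and average
is the conventional default for correlation distances. Dendrograms
serialize to Newick.

Repeat-class methylation is operationalized as the in-class tag share of
the enriched track versus the input: the 2×2 table (in/out of class ×
enriched/input) gives a two-sided Fisher exact p, and per-element
length-and-library-normalized densities give a Welch t-test p. Both are
reported because neither statistic is canonical for this assay.

## Expression and candidates

RPKM = count·10⁹/(length_bp · total mapped). The low-expression filter
keeps a transcript iff any sample reaches RPKM ≥ 1 (exactly 1 is kept:
"less than 1" is the drop rule). Differential expression across groups is
one-way ANOVA on log₂(RPKM+1) — routine, included to complete the join.
The candidate cascade is monotone by construction: TSS window (−2 kb/+1 kb)
→ island-or-promoter evidence within 1 kb upstream → optional silencing
join. The silencing rule (mean RPKM in unmethylated lines ≥ 2× mean in
methylated lines, and above the low-expression threshold) is an explicit
free parameter; no numeric rule is inherited from the source procedure.

## Networks

The co-expression graph is the induced subgraph of a user-supplied edge
table on the query genes (edge tables stand in for live interaction-
database queries); query genes with no internal edge are reported as
unconnected. "The network" is the largest connected component, ties broken
by smallest member id. The power-law fit regresses log₁₀ p(k) on log₁₀ k
over observed positive degrees and reports the slope as γ (so a decaying
distribution has γ < 0) with the squared Pearson correlation as r²;
degree-zero nodes are excluded. Least squares was chosen over maximum
likelihood because the downstream quantity of interest is the (γ, r²) pair
of the regression itself. Module expansion adds all first-degree
interaction neighbors of any seed member, keeping seed/added provenance.
Term enrichment is a one-sided hypergeometric tail with BH adjustment
across terms (over-representation); the repeat module deliberately uses
two-sided Fisher instead, because depletion is meaningful there.

## The simulator

The synthetic genome defaults to 4 chromosomes × 2 Mb, 400 genes, 2000 CpG
islands and 14 repeat classes × 40 elements — large enough for stable
statistics, generated in under a second. Gene bodies never overlap
(stick-breaking placement of the free space); 70% of genes carry a
TSS-centred island; island lengths come from a 50/50 normal mixture with
modes 275 and 450 bp (sd 40); repeats avoid exons and islands so truth
intervals stay disjoint.

Methylation truth is continuous in [0,1], Beta-distributed (concentration
30) around stage-dependent means: islands shorter than 270 bp average 0.30
(melanocyte) → 0.15 (stage I) → 0.88 (stage III/IV); longer islands 0.30 →
0.15 → 0.40; 11 repeat classes fall from ~0.6 to 0.25 in the late stages
while simple repeats, LINE-1 and Alu rise from 0.3 to 0.8. Cell lines
sharing a stage share a random substream, so same-stage lines have
identical truth. The melanocyte→stage-I drop encodes early global
hypomethylation; the late-stage short-island jump encodes the
hypermethylation of short island tracts that the signature analysis
targets.

Tags: input is uniform Poisson at 0.01 tags/bp per replicate; inside a
methylated interval the enriched rate is multiplied by 1 + m·(E−1) with
enrichment factor E = 10 — E is a free parameter of the capture chemistry,
not a measured value. Two technical replicates are simulated and pooled
per track, matching the pooling step of the sequencing protocol. Tags get
random strands 50/50; calling ignores strand.

Expression: per-gene lognormal baselines, expected counts proportional to
baseline · length · 2^(−4·m) where m is the promoter-island methylation
level, Poisson-sampled at 2×10⁵ reads per line; 10% of transcripts get a
~10⁻⁴ baseline so they fall below RPKM 1 everywhere and exercise the
filter. Co-expression edge tables embed a configuration-model subnetwork
with p(k) ∝ k^−1.6 over 85% of the genes; interaction tables plant ≥3-member
cliques with external first-degree neighbors.

What the simulator does not emulate: read sequences (no FASTQ, no error
model, no mappability structure), fragment-length variation, GC or
copy-number bias, multi-isoform genes (one transcript per gene by
default), overlapping genes, and correlated methylation between
neighboring islands. Passing tests therefore demonstrate the correctness
and statistical behaviour of the analysis under its stated model, not
robustness to alignment artifacts or real-genome covariate structure.

## Numerical choices and degenerate inputs

Poisson tails use the survival function (stable to below 10⁻³⁰⁰); BED
scores are −10·log₁₀p capped at 1000, with p = 0 mapping to the cap.
Empty tag tracks produce all-zero coverage, not errors; an empty peak list
writes a valid header-only BED. A zero-library control, non-positive λ,
unknown stage labels, malformed BED/BED12/GTF lines (reported with file
and line number) and infeasible interval placement all raise explicit
errors. All randomness flows from one root seed through named
`numpy.random.default_rng` substreams per module, cell line and replicate;
reruns are byte-identical, which the manifest checksums make observable.

## Problem sizes in the checks

The recovery and false-positive measurements use the default 4×2 Mb
configuration over 20 seeds (~8 000 highly methylated islands in total);
the clustering check uses a 2×1 Mb genome with 120 genes per seed over 20
seeds; configuration-model power-law fits use 2000 nodes per seed. These
sizes give stable statistics while keeping the whole suite and the
acceptance script fast.
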