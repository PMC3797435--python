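"""Integrate promoter methylation with expression and derive candidates.

RPKM is computed per transcript, transcripts below RPKM 1 in every line are
filtered out, demethylation-reversible promoter regions are derived by
comparing treated vs untreated peak sets, and the candidate gene cascade
keeps genes with (1) a peak near the TSS, (2) CpG-island evidence 1 kb
upstream, and (3) expression silenced in the methylated lines.
"""

from methylscape import peaks
from methylscape.expression import (candidate_gene_set, compute_rpkm,
                                    filter_low_expression, reversible_regions)
from methylscape.synthetic import (DEFAULT_STAGE_PROFILE, MethylationTruth,
                                   SyntheticGenomeConfig,
                                   assign_methylation_states, generate_genome,
                                   simulate_expression, simulate_tags)

ann = generate_genome(SyntheticGenomeConfig(seed=1))
truth = assign_methylation_states(ann, DEFAULT_STAGE_PROFILE, seed=1)

counts, lengths = simulate_expression(ann, truth, seed=1)
rpkm = compute_rpkm(counts, lengths)
kept = filter_low_expression(rpkm, threshold=1.0)
print(f"transcripts: {len(rpkm)}, expressed (any RPKM >= 1): {len(kept)}")


def call(t, seed):
    enriched, control = simulate_tags(ann, t, "WM1552C", seed=seed)
    cov = peaks.build_coverage(enriched, 100, ann.chrom_lengths)
    ctl = peaks.build_coverage(control, 100, ann.chrom_lengths)
    return [c.interval for c in peaks.call_peaks(cov, ctl)]


untreated_peaks = call(truth, 1)
erased = MethylationTruth(state={k: 0.0 for k in truth.state},
                          stage_profile=truth.stage_profile)
treated_peaks = call(erased, 2)
rev = [r.interval for r in reversible_regions(untreated_peaks, treated_peaks)
       if r.reversal]
print(f"methylated regions reversible by demethylating treatment: {len(rev)}")

res = candidate_gene_set(
    rev, ann.genes, ann.islands, expression_rpkm=kept,
    methylated_lines=["WM1552C", "A375", "SKMEL2"],
    unmethylated_lines=["HEM", "WM793B"],
)
print(f"cascade: {res.stage_counts}")
print(f"candidate genes: {len(res.genes)} (first five: {res.genes[:5]})")
# The survivors carry a reversible methylated promoter island and are
# expressed in the unmethylated lines but silenced in the methylated ones.
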