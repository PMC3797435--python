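"""Derive the late-stage-specific methylation signature.

Peaks are called per cell line, matched across lines by reciprocal overlap
(>= 50% of each region), and the regions shared by both stage IV lines but
absent from the melanocyte, stage I and stage III lines form the
stage-IV-specific core.
"""

from methylscape import peaks
from methylscape.signatures import (GENE_SPAN_PRESET, PeakSetCollection,
                                    derive_stage_specific,
                                    map_regions_to_genes, venn_counts)
from methylscape.synthetic import (DEFAULT_STAGE_PROFILE,
                                   SyntheticGenomeConfig,
                                   assign_methylation_states, generate_genome,
                                   simulate_tags)

ann = generate_genome(SyntheticGenomeConfig(seed=1))
truth = assign_methylation_states(ann, DEFAULT_STAGE_PROFILE, seed=1)

sets = {}
control_cov = None
for line in sorted(DEFAULT_STAGE_PROFILE):
    enriched, control = simulate_tags(ann, truth, line, seed=1)
    cov = peaks.build_coverage(enriched, 100, ann.chrom_lengths)
    if control_cov is None:
        control_cov = peaks.build_coverage(control, 100, ann.chrom_lengths)
    sets[line] = [c.interval for c in peaks.call_peaks(cov, control_cov)]
    print(f"{line:8s}: {len(sets[line])} peaks")

coll = PeakSetCollection(sets=sets)
counts = venn_counts(coll, labels=["A375", "SKMEL2"])
print(f"\nstage IV lines share {counts.get((True, True), 0)} regions "
      f"of {sum(counts.values())} union regions")

specific = derive_stage_specific(coll, ["A375", "SKMEL2"],
                                 ["HEM", "WM793B", "WM1552C"])
genes, _ = map_regions_to_genes(specific, ann.genes, **GENE_SPAN_PRESET)
print(f"stage-IV-specific regions: {len(specific)}, "
      f"mapping to {len(genes)} genes")
# These regions are methylated only in the metastatic lines: candidate
# progression markers.
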