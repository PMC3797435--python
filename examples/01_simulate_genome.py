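"""Generate a toy methylome study: genome, annotations and methylation truth.

The simulator builds a 4 x 2 Mb genome with 400 genes, 2000 CpG islands
drawn from a bimodal length mixture (modes ~275 and ~450 bp) and 14 repeat
classes, then assigns stage-dependent methylation levels to five cell lines
(one melanocyte, one stage I, one stage III, two stage IV).
"""

import numpy as np

from methylscape.synthetic import (DEFAULT_STAGE_PROFILE,
                                   SyntheticGenomeConfig,
                                   assign_methylation_states, generate_genome)

config = SyntheticGenomeConfig(seed=1)
ann = generate_genome(config)
truth = assign_methylation_states(ann, DEFAULT_STAGE_PROFILE, seed=1)

lengths = np.array([iv.length for iv in ann.islands])
print(f"genome: {len(ann.chrom_lengths)} chromosomes, "
      f"{ann.genome_size/1e6:.0f} Mb total")
print(f"genes: {len(ann.genes)}, islands: {len(ann.islands)}, "
      f"repeats: {len(ann.repeats)}")
print(f"island length quartiles: {np.percentile(lengths, [25, 50, 75])}")

short = [iv.name for iv in ann.islands if iv.length < 270]
for line in sorted(DEFAULT_STAGE_PROFILE):
    mean = np.mean([truth.level(line, n) for n in short])
    stage = DEFAULT_STAGE_PROFILE[line]
    print(f"  {line:8s} (stage {stage:10s}): "
          f"mean methylation of short islands = {mean:.2f}")
# Short islands are hypomethylated in the stage-I line and strongly
# hypermethylated in the stage-III/IV lines, the progression the analysis
# is designed to detect.
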