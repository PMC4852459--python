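"""Chromosomal layout statistics of a simulated family.

Prints the group-by-chromosome contingency table, the fraction of the
family on the main cluster chromosome, and the end-proximity fraction of
the remaining genes (how many sit within 15% of a chromosome end).
"""

from nlrevo.famsim import SimConfig, simulate_family
from nlrevo.genomelayout import end_proximity, group_chromosome_table, relative_position

cfg = SimConfig(seed=14)
ds = simulate_family(cfg)

tab = group_chromosome_table(ds.loci)
print("genes per (group, chromosome):")
print(tab.to_string(float_format=lambda v: f"{v:.2f}"))

designated = next(iter(cfg.chrom_lengths))
print(f"\n{tab.loc['fraction', designated]:.0%} of the family sits on "
      f"{designated} (the tandem cluster)")

ep = end_proximity(ds.loci, cfg.chrom_lengths, threshold=0.15,
                   exclude={designated})
print(f"outside {designated}: {ep.n_within}/{ep.n_total} genes "
      f"({ep.fraction:.0%}) lie within 15% of a chromosome end")

sample = ds.loci[-1]
rel = relative_position(sample, cfg.chrom_lengths[sample.chrom])
print(f"e.g. {sample.id} sits at relative position {rel:.2f} on {sample.chrom}")
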