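"""Per-domain dN/dS contrast: the gene-conversion signature.

Computes all pairwise divergences for the NACHT and B30.2 domains of a
simulated family and prints the group-by-group median dS and omega
matrices.  The diagnostic pattern: NACHT dS is tiny within groups but large
between them (conversion homogenises only within groups), while B30.2 dS is
uniformly tiny (conversion crosses group boundaries) with median omega > 1
(positive selection on the recognition domain).
"""

from nlrevo.codondiv import CodonAlignment, domain_slice, group_median_matrix
from nlrevo.famsim import SimConfig, simulate_family

ds = simulate_family(SimConfig(seed=7))
ids = ds.gene_ids
aln = CodonAlignment(
    ids=ids, rows=[ds.sequences[g] for g in ids], partitions=ds.partitions
)

for dom in ("nacht", "b30.2"):
    gm = group_median_matrix(domain_slice(aln, dom), ds.group_map)
    print(f"\n=== {dom} domain ===")
    print("median dS (diagonal = within-group):")
    print(gm.median_dS.round(3).to_string())
    print("median dN/dS:")
    print(gm.median_omega.round(2).to_string())
    print(f"saturated pairs dropped: {int(gm.n_dropped.values.sum()) // 2}")

print(
    "\nReading: within-group NACHT dS ~0.05 vs between-group ~1 means the "
    "groups are old but internally homogenised; flat, low B30.2 dS plus "
    "omega > 1 means cross-group conversion spreads positively selected "
    "variants family-wide."
)
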