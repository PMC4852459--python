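"""Run the divergence pipeline on a real curated dataset.

The zebrafish NLR-B30.2 study deposited its 368 curated genes (protein
alignment, CDS and locus table) as supplementary material.  Given those
files this script reproduces the published within/between-group median
dN/dS table with the iterative kappa-weighted estimator, plus the
chromosome-4 count and end-proximity fractions.  It needs four local files
(no downloads are performed here):

    proteins.aln.fasta   aligned proteins (gaps '-')
    cds.fasta            unaligned coding sequences, same ids
    groups.tsv           gene id <tab> group label (e.g. 1, 2a, 3a, 3b)
    partitions.yaml      {nacht: [start, end], b30.2: [start, end]}
                         1-based codon columns of the two domain exons
    loci.bed + chrom.sizes   for the layout statistics (optional)

Usage: python examples/reproduce_published_table.py DATA_DIR
"""

import sys
from pathlib import Path

from nlrevo.codondiv import (
    backtranslate,
    domain_slice,
    group_median_matrix,
    read_fasta,
    read_group_map,
    read_partitions,
)
from nlrevo.genomelayout import end_proximity, group_chromosome_table, read_bed, read_chrom_sizes

if len(sys.argv) != 2:
    sys.exit(__doc__)
data = Path(sys.argv[1])
needed = ["proteins.aln.fasta", "cds.fasta", "groups.tsv", "partitions.yaml"]
missing = [f for f in needed if not (data / f).exists()]
if missing:
    sys.exit(f"missing input files in {data}: {missing}\n\n{__doc__}")

proteins = read_fasta(data / "proteins.aln.fasta")
cds = dict(read_fasta(data / "cds.fasta"))
groups = read_group_map(data / "groups.tsv")
partitions = read_partitions(data / "partitions.yaml")

aln = backtranslate(proteins, cds, partitions=partitions)
for dom in partitions:
    gm = group_median_matrix(domain_slice(aln, dom), groups, estimator="myn")
    print(f"\n=== {dom}: median dN ===")
    print(gm.median_dN.round(3).to_string())
    print(f"=== {dom}: median dS ===")
    print(gm.median_dS.round(3).to_string())
    print(f"=== {dom}: median dN/dS ===")
    print(gm.median_omega.round(3).to_string())

if (data / "loci.bed").exists() and (data / "chrom.sizes").exists():
    recs = read_bed(data / "loci.bed", species="zebrafish", group_from_name=True)
    sizes = read_chrom_sizes(data / "chrom.sizes")
    tab = group_chromosome_table(recs)
    print("\ngenes per chromosome ('all' row):")
    print(tab.loc["all"].to_string())
    ep = end_proximity(recs, sizes, threshold=0.15, exclude={"4", "chr4"})
    print(f"outside chromosome 4: {ep.fraction:.0%} within 15% of ends")
    ep4 = end_proximity([r for r in recs if r.chrom in {"4", "chr4"}], sizes)
    print(f"on chromosome 4: {ep4.fraction:.0%} within 15% of ends")
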