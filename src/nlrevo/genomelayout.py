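"""Chromosomal distribution statistics for multigene families.

Large immune gene families are often tandem-clustered and biased toward
chromosome ends.  This module quantifies that layout: normalized gene
positions along a chromosome, the fraction of genes falling within a
terminal window (default 15% of each end), and group-by-chromosome
contingency tables.

Conventions: gene position is the interval midpoint; BED coordinates are
0-based half-open throughout; records on chromosomes of unknown length are
reported separately and excluded from denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GeneRecord",
    "relative_position",
    "end_proximity",
    "EndProximity",
    "group_chromosome_table",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
]


@dataclass(frozen=True)
class GeneRecord:
    """One family member: id, labels, and its genomic interval (0-based,
    half-open)."""

    id: str
    species: str
    group: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.id}: invalid interval [{self.start},{self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"{self.id}: strand must be '+', '-' or '.'")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def relative_position(rec: GeneRecord, chrom_len: int) -> float:
    """Midpoint of the gene as a fraction of chromosome length, in [0,1]."""
    if chrom_len is None or chrom_len <= 0:
        raise ValueError(f"{rec.id}: missing or non-positive chromosome length")
    if rec.end > chrom_len:
        raise ValueError(
            f"{rec.id}: interval end {rec.end} beyond chromosome length {chrom_len}"
        )
    return rec.midpoint / chrom_len


@dataclass
class EndProximity:
    """Result of :func:`end_proximity`.

    ``fraction`` is NaN (and ``defined`` False) when no gene survives
    exclusion/resolution.
    """

    fraction: float
    n_within: int
    n_total: int
    flags: pd.DataFrame
    unresolved: list[str] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return self.n_total > 0


def end_proximity(
    recs: list[GeneRecord],
    chroms: dict[str, int],
    threshold: float = 0.15,
    exclude: set[str] | None = None,
) -> EndProximity:
    """Fraction of genes whose midpoint lies within ``threshold`` of either
    chromosome end.

    ``exclude`` removes whole chromosomes (e.g. the one carrying the main
    cluster) before counting; genes on chromosomes absent from ``chroms``
    are listed in ``unresolved`` and excluded from the denominator.
    """
    if not 0 <= threshold <= 0.5:
        raise ValueError("threshold must be in [0, 0.5]")
    exclude = exclude or set()
    rows = []
    unresolved = []
    for rec in recs:
        if rec.chrom in exclude:
            continue
        if rec.chrom not in chroms:
            unresolved.append(rec.id)
            continue
        rel = relative_position(rec, chroms[rec.chrom])
        dist_to_end = min(rel, 1.0 - rel)
        rows.append(
            {
                "id": rec.id,
                "chrom": rec.chrom,
                "relpos": rel,
                "end_distance": dist_to_end,
                "within": dist_to_end <= threshold,
            }
        )
    flags = pd.DataFrame(rows, columns=["id", "chrom", "relpos", "end_distance", "within"])
    n_total = len(flags)
    n_within = int(flags["within"].sum()) if n_total else 0
    fraction = n_within / n_total if n_total else float("nan")
    return EndProximity(
        fraction=fraction,
        n_within=n_within,
        n_total=n_total,
        flags=flags,
        unresolved=unresolved,
    )


def group_chromosome_table(recs: list[GeneRecord]) -> pd.DataFrame:
    """Contingency table of gene counts per (group, chromosome).

    Includes an 'all' margin row/column; per-chromosome fractions of the
    family are in the 'fraction' row.
    """
    df = pd.DataFrame({"group": [r.group for r in recs], "chrom": [r.chrom for r in recs]})
    if df.empty:
        return pd.DataFrame()
    table = pd.crosstab(df["group"], df["chrom"], margins=True, margins_name="all")
    total = len(recs)
    table.loc["fraction"] = table.loc["all"] / total
    return table


# ---------------------------------------------------------------------------
# file formats


def read_bed(path, species: str = "", group_from_name: bool = False) -> list[GeneRecord]:
    """BED6 (or BED4) -> GeneRecords.

    With ``group_from_name`` the name field is split on the last '|' into
    ``id|group``.
    """
    recs = []
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    for row in df.itertuples(index=False):
        fields = list(row) + ["."] * (6 - len(row))
        chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
        strand = fields[5] if fields[5] in {"+", "-"} else "."
        if group_from_name and "|" in name:
            gene_id, group = name.rsplit("|", 1)
        else:
            gene_id, group = name, ""
        recs.append(
            GeneRecord(
                id=gene_id, species=species, group=group,
                chrom=chrom, start=start, end=end, strand=strand,
            )
        )
    return recs


def write_bed(recs: list[GeneRecord], path, group_in_name: bool = False) -> None:
    with open(path, "w") as fh:
        for r in sorted(recs, key=lambda r: (r.chrom, r.start)):
            name = f"{r.id}|{r.group}" if group_in_name else r.id
            strand = r.strand if r.strand in {"+", "-"} else "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t{strand}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    """UCSC chrom.sizes dialect: two tab-separated columns, name and bp."""
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str, 1: int})
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
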