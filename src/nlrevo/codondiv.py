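"""Codon alignments and pairwise dN/dS estimation.

The central objects are :class:`CodonAlignment` (an in-frame nucleotide
alignment with named domain partitions) and :class:`PairDivergence` (dN, dS
and their ratio for one pair of rows).  Two estimators are provided:

* :func:`ng86_pair` — Nei & Gojobori (1986) counting with Jukes–Cantor
  correction.  Exactly specified, hand-checkable, used as the default and as
  the substrate of the simulation-recovery tests.
* :func:`myn_pair` — the iterative Yang & Nielsen (2000)-style estimator with
  HKY transition/transversion and codon-frequency weighting, for data where
  ignoring the transition bias is too crude.

Group-wise aggregation into the within/between-group median matrices used to
summarise multigene-family divergence is done by :func:`group_median_matrix`.

Conventions (documented, they matter for reproducing published numbers):

* stop-codon neighbours count as nonsynonymous sites, so S + N = 3 per codon;
* mutational pathways through stop codons are excluded from pathway averaging;
* codon columns with a gap or ambiguity on either side of a pair are dropped
  (pairwise complete-codon deletion);
* saturated pairs (Jukes–Cantor log argument <= 0) are flagged invalid;
* omega is NaN (an invalid ratio, not infinity) when dS = 0;
* medians use the conventional midpoint rule for even counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from ._codons import SENSE_CODONS, SN_SITES, STOP_CODONS, pair_sdnd, translate_cds
from ._yn00 import yn00_pair

__all__ = [
    "CodonAlignment",
    "PairDivergence",
    "GroupMatrix",
    "backtranslate",
    "ng86_pair",
    "myn_pair",
    "domain_slice",
    "group_median_matrix",
    "read_fasta",
    "read_group_map",
    "read_partitions",
]

_VALID_CODONS = frozenset(SENSE_CODONS)


class TranslationMismatch(ValueError):
    """Protein row does not match the translation of its CDS."""


@dataclass
class CodonAlignment:
    """In-frame nucleotide alignment; gaps only as whole codons '---'.

    ``partitions`` maps domain name -> (start, end) codon columns, 1-based
    inclusive.
    """

    ids: list[str]
    rows: list[str]
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        if lengths and next(iter(lengths)) % 3:
            raise ValueError("row length is not a multiple of 3")
        n_codons = self.n_codons
        for name, (lo, hi) in self.partitions.items():
            if not (1 <= lo <= hi <= n_codons):
                raise ValueError(
                    f"partition {name!r}=({lo},{hi}) outside 1..{n_codons}"
                )

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3 if self.rows else 0

    def row(self, gene_id: str) -> str:
        return self.rows[self.ids.index(gene_id)]


@dataclass(frozen=True)
class PairDivergence:
    """dN/dS summary for one sequence pair.

    ``valid`` is False when no codons were comparable or a Jukes–Cantor
    correction was undefined (saturation).  ``omega`` is NaN when dS = 0 or
    the pair is invalid.
    """

    dN: float
    dS: float
    omega: float
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    n_codons: int
    valid: bool


def _jc_correct(p: float) -> float | None:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return None
    return -0.75 * math.log(arg)


def _codon_list(row: str) -> list[str | None]:
    """Split a row into codons; None marks gap/ambiguous/stop codons."""
    out: list[str | None] = []
    for i in range(0, len(row), 3):
        codon = row[i : i + 3].upper()
        out.append(codon if codon in _VALID_CODONS else None)
    return out


def ng86_pair(row_a: str, row_b: str) -> PairDivergence:
    """Nei–Gojobori (1986) pairwise dN/dS with Jukes–Cantor correction.

    Site counts are averaged over the two sequences; codons differing at
    several positions average observed differences over all stop-free
    orderings of single-base steps.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    if len(row_a) % 3:
        raise ValueError("row length is not a multiple of 3")
    ca, cb = _codon_list(row_a), _codon_list(row_b)
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for x, y in zip(ca, cb):
        if x is None or y is None:
            continue
        n_codons += 1
        sx, nx = SN_SITES[x]
        sy, ny = SN_SITES[y]
        S += (sx + sy) / 2.0
        N += (nx + ny) / 2.0
        sd, nd = pair_sdnd(x, y)
        Sd += sd
        Nd += nd
    if n_codons == 0:
        raise ValueError("no comparable codons between the two rows")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jc_correct(pS)
    dN = _jc_correct(pN)
    valid = dS is not None and dN is not None
    dS_v = dS if dS is not None else math.nan
    dN_v = dN if dN is not None else math.nan
    omega = dN_v / dS_v if valid and dS_v > 0 else math.nan
    return PairDivergence(
        dN=dN_v, dS=dS_v, omega=omega, S_sites=S, N_sites=N,
        Sd=Sd, Nd=Nd, n_codons=n_codons, valid=valid,
    )


def myn_pair(row_a: str, row_b: str, max_iter: int = 50) -> PairDivergence:
    """Iterative kappa/codon-frequency weighted dN/dS (Yang–Nielsen 2000 style).

    Transition/transversion bias (HKY form) and observed codon frequencies
    weight the site counting; kappa is estimated from nondegenerate and
    fourfold-degenerate positions; distances are corrected with the F84
    formula per site class and iterated to convergence.  Returns
    ``valid=False`` on non-convergence after ``max_iter`` iterations or on a
    degenerate correction.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    if len(row_a) % 3:
        raise ValueError("row length is not a multiple of 3")
    ca, cb = _codon_list(row_a), _codon_list(row_b)
    pairs = [(x, y) for x, y in zip(ca, cb) if x is not None and y is not None]
    if not pairs:
        raise ValueError("no comparable codons between the two rows")
    return yn00_pair(pairs, max_iter=max_iter)


def backtranslate(
    protein_alignment,
    cds_map: dict[str, str],
    partitions: dict[str, tuple[int, int]] | None = None,
) -> CodonAlignment:
    """Thread coding sequences onto a protein alignment (tranalign-style).

    ``protein_alignment`` is an iterable of ``(id, aligned_protein)`` pairs or
    Bio.SeqRecord objects.  Each amino-acid column becomes one codon column;
    a gap becomes '---'.  A trailing stop codon on the CDS is tolerated and
    dropped.  Raises :class:`TranslationMismatch` naming the id and residue
    index on any disagreement, KeyError for a missing CDS.
    """
    ids: list[str] = []
    rows: list[str] = []
    for rec in protein_alignment:
        if hasattr(rec, "id"):
            gene_id, prot = rec.id, str(rec.seq)
        else:
            gene_id, prot = rec
        if gene_id not in cds_map:
            raise KeyError(f"no CDS provided for aligned id {gene_id!r}")
        cds = cds_map[gene_id].upper()
        if len(cds) % 3:
            raise TranslationMismatch(f"{gene_id}: CDS length not a multiple of 3")
        if cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        residues = prot.replace("-", "")
        if len(cds) != 3 * len(residues):
            raise TranslationMismatch(
                f"{gene_id}: CDS encodes {len(cds) // 3} residues, "
                f"alignment has {len(residues)}"
            )
        translated = translate_cds(cds)
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        row = []
        k = 0
        for col, aa in enumerate(prot):
            if aa == "-":
                row.append("---")
                continue
            if translated[k] != aa.upper():
                raise TranslationMismatch(
                    f"{gene_id}: residue {k + 1} is {aa!r} in the alignment but "
                    f"codon {codons[k]} translates to {translated[k]!r}"
                )
            row.append(codons[k])
            k += 1
        ids.append(gene_id)
        rows.append("".join(row))
    return CodonAlignment(ids=ids, rows=rows, partitions=dict(partitions or {}))


def domain_slice(aln: CodonAlignment, domain: str) -> CodonAlignment:
    """Restrict an alignment to one named domain partition."""
    if domain not in aln.partitions:
        raise KeyError(
            f"unknown domain {domain!r}; have {sorted(aln.partitions)}"
        )
    lo, hi = aln.partitions[domain]
    if hi < lo:
        raise ValueError(f"domain {domain!r} has an empty interval ({lo},{hi})")
    rows = [r[(lo - 1) * 3 : hi * 3] for r in aln.rows]
    return CodonAlignment(
        ids=list(aln.ids), rows=rows, partitions={domain: (1, hi - lo + 1)}
    )


@dataclass
class GroupMatrix:
    """Within/between-group median divergence matrices.

    Each DataFrame is indexed by group label both ways; the diagonal holds
    within-group medians.  ``n_dropped`` counts pairs flagged invalid
    (saturated); the omega median additionally excludes dS = 0 pairs.
    """

    labels: list[str]
    median_dN: pd.DataFrame
    median_dS: pd.DataFrame
    median_omega: pd.DataFrame
    n_pairs: pd.DataFrame
    n_dropped: pd.DataFrame

    def to_tsv(self, path, what: str = "dS") -> None:
        getattr(self, f"median_{what}").to_csv(path, sep="\t")


_ESTIMATORS = {"ng86": ng86_pair, "myn": myn_pair}


def pairwise_divergences(
    aln: CodonAlignment,
    group_map: dict[str, str],
    estimator: str = "ng86",
) -> pd.DataFrame:
    """Divergence for every unordered pair of alignment rows.

    One row per pair with ids, group labels (sorted so ``group_a <=
    group_b``), dN, dS, omega and the valid flag — the all-pairwise table
    that group medians are computed from.  Only genes present in
    ``group_map`` are compared.
    """
    try:
        pair_fn = _ESTIMATORS[estimator]
    except KeyError:
        raise ValueError(f"estimator must be one of {sorted(_ESTIMATORS)}") from None
    members = [(i, g) for i, g in enumerate(aln.ids) if g in group_map]
    rows = []
    for a in range(len(members)):
        ia, ga = members[a]
        for b in range(a + 1, len(members)):
            ib, gb = members[b]
            la, lb = sorted((group_map[ga], group_map[gb]))
            pd_ = pair_fn(aln.rows[ia], aln.rows[ib])
            rows.append(
                {
                    "id_a": ga, "id_b": gb, "group_a": la, "group_b": lb,
                    "within": la == lb, "dN": pd_.dN, "dS": pd_.dS,
                    "omega": pd_.omega, "valid": pd_.valid,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["id_a", "id_b", "group_a", "group_b", "within",
                 "dN", "dS", "omega", "valid"],
    )


def group_median_matrix(
    aln: CodonAlignment,
    group_map: dict[str, str],
    estimator: str = "ng86",
) -> GroupMatrix:
    """All-pairs divergence aggregated into group-by-group median matrices.

    Every unordered pair of alignment rows (both present in ``group_map``) is
    computed exactly once; medians are over valid pairs.  A group with fewer
    than two members yields NaN on its diagonal rather than an error.
    """
    table = pairwise_divergences(aln, group_map, estimator=estimator)
    labels = sorted({group_map[g] for g in aln.ids if g in group_map})
    n = len(labels)

    def _empty():
        return pd.DataFrame(np.full((n, n), np.nan), index=labels, columns=labels)

    median_dN, median_dS, median_om = _empty(), _empty(), _empty()
    n_pairs = pd.DataFrame(np.zeros((n, n), dtype=int), index=labels, columns=labels)
    n_dropped = n_pairs.copy()
    if not table.empty:
        for (la, lb), cell in table.groupby(["group_a", "group_b"]):
            n_pairs.loc[la, lb] = n_pairs.loc[lb, la] = len(cell)
            n_dropped.loc[la, lb] = n_dropped.loc[lb, la] = int((~cell["valid"]).sum())
            ok = cell[cell["valid"]]
            if len(ok):
                median_dN.loc[la, lb] = median_dN.loc[lb, la] = ok["dN"].median()
                median_dS.loc[la, lb] = median_dS.loc[lb, la] = ok["dS"].median()
            om = ok["omega"].dropna()
            if len(om):
                median_om.loc[la, lb] = median_om.loc[lb, la] = om.median()
    return GroupMatrix(
        labels=labels,
        median_dN=median_dN,
        median_dS=median_dS,
        median_omega=median_om,
        n_pairs=n_pairs,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# file formats


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_group_map(path) -> dict[str, str]:
    """Two-column TSV (gene id, group label) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_partitions(path) -> dict[str, tuple[int, int]]:
    """YAML {domain: [start_codon, end_codon]} (1-based inclusive)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {name: (int(v[0]), int(v[1])) for name, v in raw.items()}
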