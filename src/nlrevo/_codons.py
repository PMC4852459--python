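"""Shared codon-level machinery: genetic code, site classes, pathway counts.

Everything here is derived once from the standard genetic code at import time
and cached in plain dicts so that pairwise estimators are cheap table lookups.
"""

from __future__ import annotations

from itertools import permutations

from Bio.Data import CodonTable

BASES = "TCAG"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("TC")

_table = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, sense codons only
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in CODON_TO_AA if set(c) <= set(BASES))
)


def is_transition(a: str, b: str) -> bool:
    """True if the single-base change a->b is a transition (purine<->purine or
    pyrimidine<->pyrimidine)."""
    return (a in PURINES) == (b in PURINES)


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS; '*' for stops. Raises on frame errors."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not a multiple of 3")
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3].upper()
        if codon in STOP_CODONS:
            out.append("*")
        else:
            aa = CODON_TO_AA.get(codon)
            out.append(aa if aa is not None else "X")
    return "".join(out)


def _neighbours(codon: str):
    for pos in range(3):
        for base in BASES:
            if base != codon[pos]:
                yield pos, base, codon[:pos] + base + codon[pos + 1 :]


def _count_sites(codon: str) -> tuple[float, float]:
    # Changes to stop codons count as nonsynonymous so S + N = 3 exactly.
    s = 0.0
    aa = CODON_TO_AA[codon]
    for _, _, nb in _neighbours(codon):
        if nb not in STOP_CODONS and CODON_TO_AA[nb] == aa:
            s += 1.0
    s /= 3.0
    return s, 3.0 - s


#: codon -> (synonymous sites, nonsynonymous sites), S + N = 3
SN_SITES: dict[str, tuple[float, float]] = {c: _count_sites(c) for c in SENSE_CODONS}


def _step_class(c1: str, c2: str) -> str:
    """'syn' or 'nonsyn' for a single-base step between two non-stop codons."""
    return "syn" if CODON_TO_AA[c1] == CODON_TO_AA[c2] else "nonsyn"


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """NG86 observed-difference counts (Sd, Nd) for one codon pair.

    Averages over all orderings of the single-base steps from c1 to c2,
    excluding orderings that pass through a stop codon.  If every ordering is
    blocked the stop-passing paths are used after all (documented fallback;
    does not occur between sense codons under the standard code, kept as a
    guard).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    valid_paths = []
    blocked_paths = []
    for order in permutations(diff):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS or cur in STOP_CODONS:
                blocked = True
                steps.append(("nonsyn", cur, nxt))
            else:
                steps.append((_step_class(cur, nxt), cur, nxt))
            cur = nxt
        (blocked_paths if blocked else valid_paths).append(steps)
    paths = valid_paths or blocked_paths
    sd = nd = 0.0
    for steps in paths:
        for cls, _, _ in steps:
            if cls == "syn":
                sd += 1.0
            else:
                nd += 1.0
    sd /= len(paths)
    nd /= len(paths)
    return sd, nd


#: (codon1, codon2) -> (Sd, Nd), pathway-averaged; built lazily (61*61 pairs)
PAIR_SDND: dict[tuple[str, str], tuple[float, float]] = {}


def pair_sdnd(c1: str, c2: str) -> tuple[float, float]:
    key = (c1, c2)
    hit = PAIR_SDND.get(key)
    if hit is None:
        hit = PAIR_SDND[key] = _pathway_counts(c1, c2)
    return hit
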