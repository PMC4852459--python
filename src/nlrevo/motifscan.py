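"""Motif-based discovery and annotation of family members.

Three capabilities, all regex-driven:

* scanning protein or DNA records (all six frames) for class patterns such
  as the Walker A P-loop consensus ``G[IV]AG[IV]AGK[TS]``;
* chaining per-sequence motif hits into candidate gene loci when they occur
  in profile order within a bp window — the screen used to find family
  members on unannotated contigs;
* counting classical C2H2 zinc-finger repeats with the PROSITE PS00028-style
  class pattern (non-overlapping, leftmost-first).

Patterns may be written either as PROSITE strings (``C-x(2,4)-C-x(3)-...``)
or as plain amino-acid class strings (``G[IV]AG[IV]AGK[TS]``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import yaml

from ._codons import translate_cds

__all__ = [
    "MotifProfile",
    "MotifHit",
    "CandidateLocus",
    "WALKER_A",
    "C2H2_PATTERN",
    "pattern_to_regex",
    "six_frame_translate",
    "FrameTranslation",
    "scan_motif",
    "scan_walker_a",
    "count_c2h2",
    "chain_hits",
    "load_profile",
]

#: family-wide Walker A consensus
WALKER_A = "G[IV]AG[IV]AGK[TS]"

#: classical C2H2 zinc finger (PROSITE PS00028-equivalent class pattern)
C2H2_PATTERN = "C-x(2,4)-C-x(3)-[LIVMFYWC]-x(8)-H-x(3,5)-H"

_AA = "ACDEFGHIKLMNPQRSTVWY"
_PROSITE_TOKEN = re.compile(
    r"x(?:\((\d+)(?:,(\d+))?\))?|\[([A-Za-z]+)\]|\{([A-Za-z]+)\}|([A-Za-z])"
)


def pattern_to_regex(pattern: str) -> str:
    """Compile a PROSITE-style or class-string motif pattern to a regex.

    PROSITE syntax (elements joined by '-'): ``x`` any residue, ``x(3)`` /
    ``x(2,4)`` repeats, ``[ABC]`` class, ``{ABC}`` negated class, plain
    letters literal.  Strings without '-' are treated as regex-like class
    strings and validated.
    """
    if "-" in pattern:
        out = []
        for element in pattern.strip().split("-"):
            m = _PROSITE_TOKEN.fullmatch(element)
            if not m:
                raise ValueError(f"bad PROSITE element {element!r} in {pattern!r}")
            lo, hi, cls, neg, lit = m.groups()
            if cls is not None:
                out.append(f"[{cls.upper()}]")
            elif neg is not None:
                out.append(f"[^{neg.upper()}]")
            elif lit is not None:
                out.append(lit.upper())
            else:
                if lo is None:
                    out.append(".")
                elif hi is None:
                    out.append(f".{{{lo}}}")
                else:
                    out.append(f".{{{lo},{hi}}}")
        return "".join(out)
    if not re.fullmatch(r"[A-Za-z\[\]\^]+", pattern):
        raise ValueError(f"unsupported motif pattern {pattern!r}")
    re.compile(pattern)  # raises on malformed classes
    return pattern.upper()


@dataclass
class MotifProfile:
    """Ordered motifs expected along a gene, with chaining constraints."""

    motifs: list[tuple[str, str]]  # (motif id, pattern)
    max_gap: int = 2000  # bp between consecutive chained hits
    min_motifs: int = 2  # distinct profile motifs needed for a locus

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError("profile needs at least one motif")
        if self.max_gap <= 0:
            raise ValueError("max_gap must be > 0")
        self.order = {mid: k for k, (mid, _) in enumerate(self.motifs)}
        self.regexes = {
            mid: re.compile(pattern_to_regex(pat)) for mid, pat in self.motifs
        }


@dataclass(frozen=True)
class MotifHit:
    """One motif match; coordinates are forward-strand bp, 0-based
    half-open, for translated DNA hits; residue indices for protein input
    (frame='protein')."""

    seq_id: str
    frame: str  # '+1'..'+3', '-1'..'-3', or 'protein'
    start: int
    end: int
    motif_id: str
    peptide: str

    @property
    def strand(self) -> str:
        return "-" if self.frame.startswith("-") else "+"


@dataclass(frozen=True)
class CandidateLocus:
    seq_id: str
    strand: str
    start: int
    end: int
    motif_ids: tuple[str, ...]
    score: int  # distinct profile motifs matched


@dataclass(frozen=True)
class FrameTranslation:
    frame: str
    protein: str
    offset: int  # frame offset on the translated strand
    seq_len: int

    def bp_span(self, res_start: int, res_end: int) -> tuple[int, int]:
        """Forward-strand bp interval of residues [res_start, res_end)."""
        lo = self.offset + 3 * res_start
        hi = self.offset + 3 * res_end
        if self.frame.startswith("-"):
            return self.seq_len - hi, self.seq_len - lo
        return lo, hi


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def six_frame_translate(dna: str) -> list[FrameTranslation]:
    """Translate all six frames; stops are '*', ambiguous codons 'X'.

    Frame coordinate maps recover forward-strand bp for any residue.
    """
    dna = dna.upper()
    if not dna:
        raise ValueError("empty sequence")
    if set(dna) - set("ACGTN"):
        raise ValueError("DNA alphabet is ACGTN")
    out = []
    rc = dna.translate(_COMPLEMENT)[::-1]
    for strand, seq in (("+", dna), ("-", rc)):
        for off in range(3):
            usable = (len(seq) - off) // 3 * 3
            prot = translate_cds(seq[off : off + usable]) if usable else ""
            out.append(
                FrameTranslation(
                    frame=f"{strand}{off + 1}",
                    protein=prot,
                    offset=off,
                    seq_len=len(dna),
                )
            )
    return out


def _looks_like_dna(seq: str) -> bool:
    letters = set(seq.upper())
    return bool(letters) and letters <= set("ACGTN")


def scan_motif(records, pattern: str, motif_id: str = "motif") -> list[MotifHit]:
    """All matches of a motif pattern in protein or DNA records.

    ``records`` is an iterable of (id, sequence); DNA records are scanned in
    all six frames with hit coordinates mapped back to the forward strand.
    """
    regex = re.compile(pattern_to_regex(pattern))
    hits = []
    for seq_id, seq in records:
        if _looks_like_dna(seq):
            for ft in six_frame_translate(seq):
                for m in regex.finditer(ft.protein):
                    lo, hi = ft.bp_span(m.start(), m.end())
                    hits.append(
                        MotifHit(
                            seq_id=seq_id, frame=ft.frame, start=lo, end=hi,
                            motif_id=motif_id, peptide=m.group(),
                        )
                    )
        else:
            for m in regex.finditer(seq.upper()):
                hits.append(
                    MotifHit(
                        seq_id=seq_id, frame="protein",
                        start=m.start(), end=m.end(),
                        motif_id=motif_id, peptide=m.group(),
                    )
                )
    return hits


def scan_walker_a(records) -> list[MotifHit]:
    """Scan for the family Walker A consensus G[IV]AG[IV]AGK[TS]."""
    return scan_motif(records, WALKER_A, motif_id="walker_a")


def count_c2h2(protein: str) -> int:
    """Number of classical C2H2 zinc-finger repeats (non-overlapping,
    leftmost-first)."""
    regex = re.compile(pattern_to_regex(C2H2_PATTERN))
    return sum(1 for _ in regex.finditer(protein.upper()))


def scan_profile(records, profile: MotifProfile) -> list[MotifHit]:
    """All hits for every motif of a profile."""
    hits = []
    for mid, pat in profile.motifs:
        hits.extend(scan_motif(records, pat, motif_id=mid))
    return hits


def chain_hits(hits: list[MotifHit], profile: MotifProfile) -> list[CandidateLocus]:
    """Greedy left-to-right chaining of motif hits into candidate loci.

    Per sequence and strand, hits are walked in strand order (descending
    forward coordinate on '-'); a hit extends the open chain if its profile
    rank is >= the previous hit's and the gap is <= ``max_gap``, otherwise a
    new chain starts.  Chains with >= ``min_motifs`` distinct motifs become
    loci; overlapping loci on the same strand are merged keeping the
    higher-scoring chain's motif list.
    """
    by_key: dict[tuple[str, str], list[MotifHit]] = {}
    for h in hits:
        if h.motif_id not in profile.order:
            continue
        by_key.setdefault((h.seq_id, h.strand), []).append(h)

    loci: list[CandidateLocus] = []
    for (seq_id, strand), group in sorted(by_key.items()):
        group.sort(key=lambda h: h.start, reverse=(strand == "-"))
        chains: list[list[MotifHit]] = []
        open_chain: list[MotifHit] = []
        for h in group:
            if open_chain:
                prev = open_chain[-1]
                gap = (
                    h.start - prev.end if strand == "+" else prev.start - h.end
                )
                in_order = profile.order[h.motif_id] >= profile.order[prev.motif_id]
                if gap <= profile.max_gap and gap >= -profile.max_gap and in_order:
                    open_chain.append(h)
                    continue
                chains.append(open_chain)
            open_chain = [h]
        if open_chain:
            chains.append(open_chain)
        for chain in chains:
            distinct = {h.motif_id for h in chain}
            if len(distinct) < profile.min_motifs:
                continue
            loci.append(
                CandidateLocus(
                    seq_id=seq_id,
                    strand=strand,
                    start=min(h.start for h in chain),
                    end=max(h.end for h in chain),
                    motif_ids=tuple(h.motif_id for h in chain),
                    score=len(distinct),
                )
            )

    # merge overlapping loci per (sequence, strand), keeping the best score
    merged: list[CandidateLocus] = []
    for key in sorted({(l.seq_id, l.strand) for l in loci}):
        group = sorted(
            (l for l in loci if (l.seq_id, l.strand) == key),
            key=lambda l: l.start,
        )
        cur = group[0]
        for nxt in group[1:]:
            if nxt.start < cur.end:  # overlap
                best = max((cur, nxt), key=lambda l: (l.score, -(l.end - l.start)))
                cur = CandidateLocus(
                    seq_id=cur.seq_id, strand=cur.strand,
                    start=min(cur.start, nxt.start),
                    end=max(cur.end, nxt.end),
                    motif_ids=best.motif_ids, score=best.score,
                )
            else:
                merged.append(cur)
                cur = nxt
        merged.append(cur)
    return merged


def load_profile(path) -> MotifProfile:
    """Load a motif profile from YAML.

    Layout::

        motifs:
          - id: walker_a
            pattern: "G[IV]AG[IV]AGK[TS]"
        max_gap: 2000
        min_motifs: 2
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    motifs = [(m["id"], m["pattern"]) for m in raw["motifs"]]
    return MotifProfile(
        motifs=motifs,
        max_gap=int(raw.get("max_gap", 2000)),
        min_motifs=int(raw.get("min_motifs", 2)),
    )
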