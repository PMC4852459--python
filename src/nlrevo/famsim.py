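"""Forward-in-time simulator of a multigene family under duplication,
domain-restricted gene conversion and site-class selection.

The simulated world mirrors what shaped the fish NLR-B30.2 family: several
gene groups whose NACHT-type domain is homogenized only *within* each group
(within-group conversion), while the B30.2-type recognition domain is
homogenized *across* groups and carries hypervariable codons under positive
selection.  Genes sit in tandem clusters biased toward chromosome ends.

All genes descend from a single family root; group identity is purely a
label plus the conversion topology — between-group divergence emerges from
generations of point substitution that cross-group conversion (where
allowed) keeps erasing.  Every stochastic event is logged, and replaying the
log on the ancestral sequences reproduces the final sequences exactly.

The substitution kernel is a proposal/acceptance scheme, not a full rate
matrix: single-nucleotide proposals are uniform, proposals creating stop
codons are rejected, synonymous proposals are accepted with probability
min(1, 1/omega) and nonsynonymous ones with min(1, omega), where omega is
the proposal site's selection class.  Only the omega asymmetry matters for
the divergence patterns this simulator exists to produce.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from ._codons import CODON_TO_AA, SENSE_CODONS, STOP_CODONS, translate_cds
from .genomelayout import GeneRecord, write_bed

__all__ = [
    "SimConfig",
    "SubstitutionEvent",
    "ConversionEvent",
    "DuplicationEvent",
    "FamilyDataset",
    "SimulationRegimeError",
    "simulate_family",
    "mutate_codon_sequence",
    "apply_conversion",
    "assign_positions",
    "replay_events",
    "motif_profile",
    "build_genome",
    "write_family",
]

#: expected accepted substitutions per codon site over the whole run above
#: which the regime is refused as saturated (dS estimates become meaningless)
SATURATION_GUARD = 1.5

#: peptide motifs embedded in the family root (codon offset within domain,
#: peptide).  The first is the Walker A P-loop consensus; the others are
#: invented conserved anchors so ordered-motif screens are testable.  Motif
#: codons evolve under omega = 0 (invariant at the protein level).
DEFAULT_MOTIFS: dict[str, list[tuple[int, str]]] = {
    "nacht": [(5, "GIAGIAGKT"), (40, "LLDGLDE")],
    "b30.2": [(10, "WEVEVS")],
}

DEFAULT_CHROM_LENGTHS = {
    "chr4": 2_000_000,
    "chr1": 1_500_000,
    "chr17": 1_200_000,
    "chr15": 1_000_000,
    "chr22": 900_000,
}


class SimulationRegimeError(ValueError):
    """Configuration implies a saturated, unusable simulation regime."""


@dataclass
class SimConfig:
    """Simulation parameters.  Defaults are the qualitative regime of the
    zebrafish family: within-group NACHT conversion, across-group B30.2
    conversion, positive selection on 20% of B30.2 codons, three quarters of
    the family tandem-clustered on one chromosome, the rest biased toward
    chromosome ends."""

    n_groups: int = 4
    genes_per_group: int = 8
    codons_per_domain: dict[str, int] = field(
        default_factory=lambda: {"nacht": 120, "b30.2": 120}
    )
    generations: int = 300
    #: expected accepted substitutions per codon site per generation
    point_sub_rate: float = 0.002
    #: domain -> (fraction_hypervariable, omega_background, omega_hyper)
    omega_profile: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "nacht": (0.0, 0.2, 4.0),
            "b30.2": (0.2, 2.0, 4.0),
        }
    )
    #: domain -> 'within_group' | 'across_groups' | 'off'
    conversion_policy: dict[str, str] = field(
        default_factory=lambda: {"nacht": "within_group", "b30.2": "across_groups"}
    )
    #: expected conversion events per gene per generation (per domain)
    conversion_rate: float = 2.5
    #: mean conversion tract length in codons (geometric, truncated at the
    #: domain boundary)
    tract_mean: float = 10.0
    #: expected duplication events per gene per generation
    duplication_rate: float = 0.0
    seed: int = 0
    embedded_motifs: dict[str, list[tuple[int, str]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_MOTIFS.items()}
    )
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    cluster_fraction: float = 0.75
    end_bias: float = 0.81
    species: str = "zebrafish"

    def validate(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.genes_per_group < 1:
            raise ValueError("genes_per_group must be >= 1")
        for name, n in self.codons_per_domain.items():
            if n < 2:
                raise ValueError(f"domain {name!r} must have >= 2 codons")
        for r in (self.point_sub_rate, self.conversion_rate, self.duplication_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if self.tract_mean < 1:
            raise ValueError("tract_mean must be >= 1 codon")
        for frac in (self.cluster_fraction, self.end_bias):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0,1]")
        for dom, (frac, wb, wh) in self.omega_profile.items():
            if not 0 <= frac <= 1:
                raise ValueError(f"{dom}: hypervariable fraction outside [0,1]")
            if wb < 0 or wh < 0:
                raise ValueError(f"{dom}: omega values must be >= 0")
        for dom, pol in self.conversion_policy.items():
            if pol not in {"within_group", "across_groups", "off"}:
                raise ValueError(f"{dom}: unknown conversion policy {pol!r}")
            if dom not in self.codons_per_domain:
                raise ValueError(f"conversion policy for unknown domain {dom!r}")
        if self.point_sub_rate * self.generations > SATURATION_GUARD:
            raise SimulationRegimeError(
                f"point_sub_rate * generations = "
                f"{self.point_sub_rate * self.generations:.3g} exceeds the "
                f"saturation guard ({SATURATION_GUARD}); divergence estimates "
                "would be saturated"
            )

    @property
    def n_codons(self) -> int:
        return sum(self.codons_per_domain.values())

    @property
    def partitions(self) -> dict[str, tuple[int, int]]:
        """Domain name -> 1-based inclusive codon interval, in declaration
        order."""
        out = {}
        pos = 1
        for name, n in self.codons_per_domain.items():
            out[name] = (pos, pos + n - 1)
            pos += n
        return out


@dataclass(frozen=True)
class SubstitutionEvent:
    generation: int
    gene: str
    position: int  # nucleotide position, 0-based
    old_base: str
    new_base: str


@dataclass(frozen=True)
class ConversionEvent:
    generation: int
    donor_gene: str
    acceptor_gene: str
    domain: str
    tract_start: int  # codon index, 0-based, alignment-wide
    tract_len: int  # codons

    def __post_init__(self) -> None:
        if self.donor_gene == self.acceptor_gene:
            raise ValueError("conversion donor and acceptor must differ")
        if self.tract_len < 1:
            raise ValueError("tract_len must be >= 1")


@dataclass(frozen=True)
class DuplicationEvent:
    generation: int
    source_gene: str
    new_gene: str


@dataclass
class FamilyDataset:
    """Everything a downstream analysis needs, plus the ground truth."""

    sequences: dict[str, str]
    group_map: dict[str, str]
    partitions: dict[str, tuple[int, int]]
    loci: list[GeneRecord]
    events: list  # ordered log of Substitution/Conversion/Duplication events
    ancestral_sequences: dict[str, str]
    site_omega: np.ndarray  # per-codon selection class
    config: SimConfig

    @property
    def conversion_events(self) -> list[ConversionEvent]:
        return [e for e in self.events if isinstance(e, ConversionEvent)]

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.sequences)

    def proteins(self) -> dict[str, str]:
        return {g: translate_cds(s) for g, s in self.sequences.items()}


# ---------------------------------------------------------------------------
# elementary operations


def _check_in_frame(seq: str) -> None:
    prot = translate_cds(seq)  # raises on frame error
    if "*" in prot:
        raise ValueError("sequence contains an internal stop codon")


def _accept_probability(omega_site: float, synonymous: bool) -> float:
    if synonymous:
        return 1.0 if omega_site == 0 else min(1.0, 1.0 / omega_site)
    return min(1.0, omega_site)


_OTHER_BASES = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


def _mutate(seq, n_events, site_omega, rng):
    """Apply exactly n_events accepted substitutions; returns (seq, events).

    ``site_omega`` is a scalar or a per-codon array.
    """
    chars = list(seq)
    n_codons = len(chars) // 3
    omega = np.broadcast_to(np.asarray(site_omega, dtype=float), (n_codons,))
    events = []
    attempts = 0
    cap = 1000 + 10000 * n_events
    while len(events) < n_events:
        attempts += 1
        if attempts > cap:
            raise RuntimeError(
                "mutation proposals exhausted; selection profile may forbid "
                "all changes"
            )
        pos = int(rng.integers(len(chars)))
        old = chars[pos]
        new = _OTHER_BASES[old][int(rng.integers(3))]
        ci = pos // 3
        codon = chars[3 * ci] + chars[3 * ci + 1] + chars[3 * ci + 2]
        cand = codon[: pos % 3] + new + codon[pos % 3 + 1 :]
        if cand in STOP_CODONS:
            continue
        synonymous = CODON_TO_AA[cand] == CODON_TO_AA[codon]
        if rng.random() < _accept_probability(float(omega[ci]), synonymous):
            chars[pos] = new
            events.append((pos, old, new))
    return "".join(chars), events


def mutate_codon_sequence(seq: str, n_events: int, site_omega, rng) -> str:
    """Apply exactly ``n_events`` accepted single-nucleotide substitutions.

    Proposals are uniform over positions and alternative bases; proposals
    creating stop codons are rejected; synonymous proposals are accepted
    with probability min(1, 1/omega), nonsynonymous with min(1, omega),
    where omega is the proposal codon's entry in ``site_omega`` (scalar or
    per-codon array).  ``rng`` is a numpy Generator.
    """
    _check_in_frame(seq)
    new_seq, _ = _mutate(seq, n_events, site_omega, rng)
    return new_seq


def apply_conversion(
    acceptor: str, donor: str, tract_start: int, tract_len: int
) -> str:
    """Copy a codon tract from donor into acceptor (non-reciprocal)."""
    if len(acceptor) != len(donor):
        raise ValueError("acceptor and donor differ in length")
    n_codons = len(acceptor) // 3
    if not (0 <= tract_start and tract_start + tract_len <= n_codons):
        raise ValueError(
            f"tract [{tract_start},{tract_start + tract_len}) outside "
            f"0..{n_codons} codons"
        )
    lo, hi = 3 * tract_start, 3 * (tract_start + tract_len)
    return acceptor[:lo] + donor[lo:hi] + acceptor[hi:]


def assign_positions(
    n_genes: int,
    chrom_lengths: dict[str, int],
    cluster_fraction: float,
    end_bias: float,
    rng,
    *,
    ids: list[str] | None = None,
    groups: dict[str, str] | None = None,
    gene_length: int = 2000,
    species: str = "zebrafish",
    designated_chrom: str | None = None,
    end_window: float = 0.15,
    group_runs: bool = False,
) -> list[GeneRecord]:
    """Place genes on chromosomes: a tandem cluster plus end-biased strays.

    ``round(cluster_fraction * n_genes)`` genes form a tandem run on the
    designated chromosome (first key by default), near its end; each
    remaining gene goes to another chromosome, with probability ``end_bias``
    its midpoint falls inside the terminal ``end_window`` of that chromosome.
    With ``group_runs`` (and a ``groups`` mapping) the remainder is placed as
    per-group tandem runs instead of individually — mirroring families whose
    smaller groups occupy their own clusters on other chromosomes.  Intervals
    never overlap and are returned sorted per chromosome.
    """
    if any(length <= 0 for length in chrom_lengths.values()):
        raise ValueError("chromosome lengths must be > 0")
    if not 0 <= cluster_fraction <= 1 or not 0 <= end_bias <= 1:
        raise ValueError("fractions must be in [0,1]")
    if n_genes == 0:
        return []
    if ids is None:
        ids = [f"gene_{i + 1:03d}" for i in range(n_genes)]
    if len(ids) != n_genes:
        raise ValueError("ids length does not match n_genes")
    groups = groups or {}
    chrom_names = list(chrom_lengths)
    designated = designated_chrom or chrom_names[0]
    n_cluster = int(round(cluster_fraction * n_genes))

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    records: list[GeneRecord] = []

    # --- tandem cluster on the designated chromosome, near its end
    if n_cluster:
        gaps = rng.integers(100, 501, size=n_cluster)
        run_len = n_cluster * gene_length + int(gaps.sum())
        L = chrom_lengths[designated]
        if run_len > L:
            raise ValueError(
                f"cannot place {n_cluster} tandem genes on {designated} "
                f"(need {run_len} bp, have {L})"
            )
        start = max(0, L - run_len - int(0.03 * L))
        pos = start
        for k in range(n_cluster):
            s, e = pos, pos + gene_length
            strand = "+" if rng.random() < 0.5 else "-"
            records.append(
                GeneRecord(
                    id=ids[k], species=species, group=groups.get(ids[k], ""),
                    chrom=designated, start=s, end=e, strand=strand,
                )
            )
            occupied[designated].append((s, e))
            pos = e + int(gaps[k])

    # --- remaining genes: end-biased placement on the other chromosomes
    others = [c for c in chrom_names if c != designated] or chrom_names
    remainder = ids[n_cluster:]
    if group_runs and groups:
        runs: list[list[str]] = []
        for gid in remainder:
            if runs and groups.get(runs[-1][-1]) == groups.get(gid):
                runs[-1].append(gid)
            else:
                runs.append([gid])
    else:
        runs = [[gid] for gid in remainder]
    for run in runs:
        gaps = rng.integers(100, 501, size=len(run))
        run_len = len(run) * gene_length + int(gaps[:-1].sum())
        placed = False
        for _ in range(200):
            chrom = others[int(rng.integers(len(others)))]
            L = chrom_lengths[chrom]
            if L <= run_len:
                continue
            if rng.random() < end_bias:
                rel = rng.uniform(0, max(0.0, end_window - run_len / L))
                left_end = rng.random() < 0.5
                start = int(rel * L) if left_end else int(L - rel * L - run_len)
            else:
                lo = end_window * L + gene_length / 2
                hi = (1.0 - end_window) * L - run_len - gene_length / 2
                if hi <= lo:
                    continue
                start = int(rng.uniform(lo, hi))
            end = start + run_len
            if start < 0 or end > L:
                continue
            if all(end <= os or start >= oe for os, oe in occupied[chrom]):
                pos = start
                for k, gid in enumerate(run):
                    s, e = pos, pos + gene_length
                    strand = "+" if rng.random() < 0.5 else "-"
                    records.append(
                        GeneRecord(
                            id=gid, species=species, group=groups.get(gid, ""),
                            chrom=chrom, start=s, end=e, strand=strand,
                        )
                    )
                    pos = e + int(gaps[k])
                occupied[chrom].append((start, end))
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place run {run[:3]}... without overlap after 200 tries"
            )
    records.sort(key=lambda r: (r.chrom, r.start))
    return records


# ---------------------------------------------------------------------------
# the simulator


def _encode_peptide(peptide: str, rng) -> str:
    by_aa: dict[str, list[str]] = {}
    for codon in SENSE_CODONS:
        by_aa.setdefault(CODON_TO_AA[codon], []).append(codon)
    out = []
    for aa in peptide:
        if aa not in by_aa:
            raise ValueError(f"cannot encode residue {aa!r}")
        choices = by_aa[aa]
        out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def _make_root(config: SimConfig, rng) -> tuple[str, np.ndarray]:
    """Family root CDS plus the per-codon omega array (hypervariable sites
    drawn here, embedded motif codons pinned to omega = 0)."""
    parts = config.partitions
    n_codons = config.n_codons
    codons = [SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))] for _ in range(n_codons)]
    omega = np.empty(n_codons)
    for dom, (lo, hi) in parts.items():
        frac, wb, wh = config.omega_profile.get(dom, (0.0, 1.0, 1.0))
        dom_idx = np.arange(lo - 1, hi)
        omega[dom_idx] = wb
        n_hyper = int(round(frac * len(dom_idx)))
        if n_hyper:
            hyper = rng.choice(dom_idx, size=n_hyper, replace=False)
            omega[hyper] = wh
    for dom, motifs in config.embedded_motifs.items():
        if dom not in parts:
            continue
        lo, _hi = parts[dom]
        for offset, peptide in motifs:
            start = lo - 1 + offset
            if start + len(peptide) > parts[dom][1]:
                raise ValueError(
                    f"motif {peptide!r} does not fit in domain {dom!r}"
                )
            enc = _encode_peptide(peptide, rng)
            for k in range(len(peptide)):
                codons[start + k] = enc[3 * k : 3 * k + 3]
                omega[start + k] = 0.0
    return "".join(codons), omega


def simulate_family(config: SimConfig) -> FamilyDataset:
    """Run the forward simulation; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    parts = config.partitions
    n_codons = config.n_codons
    root, site_omega = _make_root(config, rng)

    group_labels = [f"g{k + 1}" for k in range(config.n_groups)]
    sequences: dict[str, str] = {}
    group_map: dict[str, str] = {}
    group_counter = dict.fromkeys(group_labels, 0)
    for lab in group_labels:
        for _ in range(config.genes_per_group):
            group_counter[lab] += 1
            gid = f"{lab}_{group_counter[lab]:03d}"
            sequences[gid] = root
            group_map[gid] = lab

    ancestral = dict(sequences)
    events: list = []

    for gen in range(1, config.generations + 1):
        gene_ids = sorted(sequences)
        by_group: dict[str, list[str]] = {}
        for g in gene_ids:
            by_group.setdefault(group_map[g], []).append(g)
        for gid in gene_ids:
            # point substitutions, drawn per domain so that selection in one
            # domain cannot displace accepted events into another
            for dom, (lo, hi) in parts.items():
                dom_codons = hi - lo + 1
                n_sub = int(rng.poisson(config.point_sub_rate * dom_codons))
                if not n_sub:
                    continue
                nt_lo, nt_hi = 3 * (lo - 1), 3 * hi
                seq = sequences[gid]
                piece, evts = _mutate(
                    seq[nt_lo:nt_hi], n_sub, site_omega[lo - 1 : hi], rng
                )
                sequences[gid] = seq[:nt_lo] + piece + seq[nt_hi:]
                for pos, old, new in evts:
                    events.append(
                        SubstitutionEvent(gen, gid, nt_lo + pos, old, new)
                    )
            # gene conversion, per domain
            for dom, policy in config.conversion_policy.items():
                if policy == "off" or dom not in parts:
                    continue
                n_conv = int(rng.poisson(config.conversion_rate))
                if not n_conv:
                    continue
                if policy == "within_group":
                    pool = [g for g in by_group[group_map[gid]] if g != gid]
                else:  # across_groups
                    pool = [g for g in gene_ids if g != gid]
                if not pool:
                    continue
                lo, hi = parts[dom]
                dom_len = hi - lo + 1
                for _ in range(n_conv):
                    donor = pool[int(rng.integers(len(pool)))]
                    offset = int(rng.integers(dom_len))
                    length = int(min(rng.geometric(1.0 / config.tract_mean),
                                     dom_len - offset))
                    tract_start = lo - 1 + offset
                    sequences[gid] = apply_conversion(
                        sequences[gid], sequences[donor], tract_start, length
                    )
                    events.append(
                        ConversionEvent(gen, donor, gid, dom, tract_start, length)
                    )
            # duplication (tandem copy)
            if config.duplication_rate:
                for _ in range(int(rng.poisson(config.duplication_rate))):
                    lab = group_map[gid]
                    group_counter[lab] += 1
                    new_id = f"{lab}_{group_counter[lab]:03d}"
                    sequences[new_id] = sequences[gid]
                    group_map[new_id] = lab
                    events.append(DuplicationEvent(gen, gid, new_id))

    ids = sorted(sequences)
    loci = assign_positions(
        len(ids),
        config.chrom_lengths,
        config.cluster_fraction,
        config.end_bias,
        rng,
        ids=ids,
        groups=group_map,
        gene_length=3 * n_codons,
        species=config.species,
        group_runs=True,
    )
    return FamilyDataset(
        sequences=sequences,
        group_map=group_map,
        partitions=parts,
        loci=loci,
        events=events,
        ancestral_sequences=ancestral,
        site_omega=site_omega,
        config=config,
    )


def replay_events(dataset: FamilyDataset) -> dict[str, str]:
    """Re-apply the event log to the ancestral sequences.

    Returns the reconstructed final sequences; equality with
    ``dataset.sequences`` is the simulator's core integrity check.
    """
    seqs = dict(dataset.ancestral_sequences)
    for ev in dataset.events:
        if isinstance(ev, SubstitutionEvent):
            s = seqs[ev.gene]
            if s[ev.position] != ev.old_base:
                raise ValueError(
                    f"replay mismatch at {ev.gene}:{ev.position} "
                    f"(log says {ev.old_base}, sequence has {s[ev.position]})"
                )
            seqs[ev.gene] = s[: ev.position] + ev.new_base + s[ev.position + 1 :]
        elif isinstance(ev, ConversionEvent):
            seqs[ev.acceptor_gene] = apply_conversion(
                seqs[ev.acceptor_gene], seqs[ev.donor_gene],
                ev.tract_start, ev.tract_len,
            )
        elif isinstance(ev, DuplicationEvent):
            seqs[ev.new_gene] = seqs[ev.source_gene]
        else:  # pragma: no cover - log is typed
            raise TypeError(f"unknown event type {type(ev)!r}")
    return seqs


def motif_profile(config: SimConfig, max_gap: int = 2000, min_motifs: int = 2):
    """MotifProfile matching the motifs this configuration embeds, in gene
    order.  The Walker A peptide is generalised to the family class pattern;
    other embedded peptides become literal patterns."""
    from .motifscan import WALKER_A, MotifProfile

    parts = config.partitions
    entries = []
    for dom, motifs in config.embedded_motifs.items():
        if dom not in parts:
            continue
        lo, _ = parts[dom]
        for offset, peptide in motifs:
            pattern = WALKER_A if peptide == "GIAGIAGKT" else peptide
            entries.append((lo - 1 + offset, f"{dom}_{offset}", pattern))
    entries.sort()
    return MotifProfile(
        motifs=[(mid, pat) for _, mid, pat in entries],
        max_gap=max_gap,
        min_motifs=min_motifs,
    )


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def build_genome(
    dataset: FamilyDataset, seed: int | None = None
) -> tuple[dict[str, str], list[GeneRecord]]:
    """Embed the simulated CDSs in random chromosomal background.

    Each locus interval receives its gene's CDS (reverse-complemented on the
    minus strand); everything else is uniform random sequence.  Returns the
    chromosome dict and the true spans (the loci themselves) for screen
    recall evaluation.
    """
    rng = np.random.default_rng(
        dataset.config.seed + 1 if seed is None else seed
    )
    genome: dict[str, str] = {}
    bases = np.array(list("ACGT"))
    for chrom, length in dataset.config.chrom_lengths.items():
        arr = rng.integers(0, 4, size=length)
        genome[chrom] = "".join(bases[arr])
    for rec in dataset.loci:
        cds = dataset.sequences[rec.id]
        if rec.end - rec.start != len(cds):
            raise ValueError(f"{rec.id}: locus length != CDS length")
        ins = cds if rec.strand != "-" else cds.translate(_COMPLEMENT)[::-1]
        s = genome[rec.chrom]
        genome[rec.chrom] = s[: rec.start] + ins + s[rec.end :]
    return genome, list(dataset.loci)


# ---------------------------------------------------------------------------
# on-disk formats


def write_family(dataset: FamilyDataset, outdir) -> None:
    """FASTA CDS + BED loci + TSV group map + JSONL events + YAML config."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "sequences.fasta", "w") as fh:
        for gid in sorted(dataset.sequences):
            fh.write(f">{gid}\n{dataset.sequences[gid]}\n")
    write_bed(dataset.loci, out / "loci.bed", group_in_name=True)
    with open(out / "groups.tsv", "w") as fh:
        for gid in sorted(dataset.group_map):
            fh.write(f"{gid}\t{dataset.group_map[gid]}\n")
    with open(out / "events.jsonl", "w") as fh:
        for ev in dataset.events:
            rec = {"type": type(ev).__name__, **dataclasses.asdict(ev)}
            fh.write(json.dumps(rec) + "\n")
    cfg = dataclasses.asdict(dataset.config)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    with open(out / "partitions.yaml", "w") as fh:
        yaml.safe_dump(
            {d: [lo, hi] for d, (lo, hi) in dataset.partitions.items()},
            fh, sort_keys=False,
        )
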