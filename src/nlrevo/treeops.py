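"""Distance and tree operations for paralogue-rich protein families.

Covers the tree side of the family analysis: Poisson-corrected amino-acid
distances, neighbor-joining construction, detection of maximal single-species
("monophyletic paralogue") clades on an unrooted tree, the recursive
reduction that repeatedly collapses such clades to one representative until
none remain, nearest-paralogue links for cluster/synteny plots, and
Robinson–Foulds incongruence between per-domain trees.

Trees are dendropy ``Tree`` objects throughout; newick import lets the
recursion run on externally built (Bayesian/ML) trees — the reduction is
builder-agnostic.

Determinism: every tie (NJ Q-matrix, argmin links, representative choice)
is broken by lexicographic label order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "SpeciesMap",
    "poisson_distance",
    "p_distance",
    "distance_matrix",
    "nj_tree",
    "same_species_clades",
    "recursive_reduce",
    "nearest_paralogue_links",
    "ParalogueLink",
    "tree_incongruence",
    "read_newick",
    "write_newick",
]

_GAPLIKE = frozenset("-.X*?")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a validity mask for undefined pairs."""

    ids: list[str]
    values: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        if not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T)
        ):
            raise ValueError("matrix is not symmetric")

    def submatrix(self, keep: list[str]) -> "DistanceMatrix":
        pos = [self.ids.index(k) for k in keep]
        return DistanceMatrix(
            ids=list(keep),
            values=self.values[np.ix_(pos, pos)],
            valid=self.valid[np.ix_(pos, pos)],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class SpeciesMap:
    """Leaf label -> species tag, with optional group labels."""

    species: dict[str, str]
    groups: dict[str, str] = field(default_factory=dict)

    def species_of(self, label: str) -> str:
        return self.species[label]

    def group_of(self, label: str) -> str | None:
        return self.groups.get(label)


def _comparable(a: str, b: str):
    for x, y in zip(a, b):
        if x in _GAPLIKE or y in _GAPLIKE:
            continue
        yield x, y


def p_distance(seq_a: str, seq_b: str) -> float:
    """Mismatch fraction over pairwise-complete sites."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    n = d = 0
    for x, y in _comparable(seq_a.upper(), seq_b.upper()):
        n += 1
        d += x != y
    if n == 0:
        raise ValueError("no comparable sites")
    return d / n


def poisson_distance(seq_a: str, seq_b: str) -> float:
    """Poisson-corrected amino-acid distance −ln(1−p); NaN when p ≥ 1."""
    p = p_distance(seq_a, seq_b)
    if p >= 1.0:
        return math.nan
    return -math.log(1.0 - p)


def distance_matrix(seqs, model: str = "poisson") -> DistanceMatrix:
    """All-pairs distance matrix from aligned proteins.

    ``seqs`` is a dict id -> sequence or an iterable of (id, seq) pairs.
    Invalid pairs (saturated or no comparable sites) become NaN with
    ``valid=False``.
    """
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    if len(items) < 2:
        raise ValueError("need at least two sequences")
    fn = {"p": p_distance, "poisson": poisson_distance}[model]
    ids = [i for i, _ in items]
    n = len(ids)
    m = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            try:
                d = fn(items[a][1], items[b][1])
            except ValueError:
                d = math.nan
            m[a, b] = m[b, a] = d
    return DistanceMatrix(ids=ids, values=m)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Negative branch lengths are clamped to zero, transferring the deficit to
    the sister edge where possible so path lengths are preserved.  The last
    three clusters are joined at a trifurcating root (unrooted convention).
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not dm.valid.all():
        bad = [
            (dm.ids[a], dm.ids[b])
            for a in range(n) for b in range(a + 1, n)
            if not dm.valid[a, b]
        ]
        raise ValueError(f"invalid distances among selected taxa: {bad[:5]}")

    taxa = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in dm.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        node.edge.length = 0.0
        nodes.append(node)
    # cluster bookkeeping: representative label = smallest leaf label, used
    # only for tie-breaking
    reps = list(dm.ids)
    D = dm.values.copy()
    active = list(range(n))

    def _clamp(node: dendropy.Node, length: float, sister: dendropy.Node | None):
        if length < 0:
            if sister is not None and sister.edge.length is not None:
                sister.edge.length = max(0.0, sister.edge.length + length)
            length = 0.0
        node.edge.length = length

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                key = (
                    Q[ai, bi],
                    *sorted((reps[active[ai]], reps[active[bi]])),
                )
                if best is None or key < best[0]:
                    best = (key, ai, bi)
        _, ai, bi = best
        i, j = active[ai], active[bi]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        _clamp(nodes[i], li, nodes[j])
        _clamp(nodes[j], lj, nodes[i])
        # distances from the new cluster to the rest
        dnew = 0.5 * (D[i, active] + D[j, active] - dij)
        D[i, active] = dnew
        D[active, i] = dnew
        D[i, i] = 0.0
        nodes[i] = parent
        reps[i] = min(reps[i], reps[j])
        active.remove(j)

    a, b = active
    root = dendropy.Node()
    if len(dm.ids) == 3:
        # nodes[a] is already the cherry parent; attach the remaining leaf
        pass
    root.add_child(nodes[a])
    root.add_child(nodes[b])
    last = D[a, b]
    # distribute the final edge: leaf-leaf joins get half each; otherwise put
    # the whole remaining length on the shallower side after clamping
    if nodes[a].is_leaf() and nodes[b].is_leaf():
        nodes[a].edge.length = last / 2
        nodes[b].edge.length = last / 2
    else:
        nodes[a].edge.length = 0.0
        nodes[b].edge.length = max(0.0, last)
    tree.seed_node = root
    # make the seed trifurcating (unrooted convention) when possible
    tree.collapse_basal_bifurcation()
    tree.update_bipartitions(suppress_unifurcations=True)
    return tree


# ---------------------------------------------------------------------------
# single-species clades and the recursive reduction


def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def same_species_clades(tree: dendropy.Tree, smap: SpeciesMap) -> list[frozenset]:
    """Maximal single-species bipartition sides with >= 2 leaves.

    Rooting-independent: for every edge both sides of the bipartition are
    candidates.  If the whole tree is one species, the full leaf set is
    returned as the single clade.
    """
    labels = _leaf_labels(tree)
    missing = [x for x in labels if x not in smap.species]
    if missing:
        raise KeyError(f"leaves missing from species map: {missing[:5]}")
    all_leaves = frozenset(labels)
    species = {x: smap.species_of(x) for x in labels}
    if len({species[x] for x in labels}) == 1 and len(labels) >= 2:
        return [all_leaves]
    candidates: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(
            lf.taxon.label for lf in node.leaf_iter()
        )
        for part in (side, all_leaves - side):
            if len(part) >= 2 and len({species[x] for x in part}) == 1:
                candidates.add(part)
    maximal = [
        c for c in candidates
        if not any(c < other for other in candidates)
    ]
    return sorted(maximal, key=lambda c: sorted(c))


def recursive_reduce(
    seqs,
    smap: SpeciesMap,
    builder=None,
    model: str = "poisson",
    max_rounds: int | None = None,
):
    """Iteratively collapse single-species clades to representatives.

    Per round: build a tree (NJ on Poisson distances by default, or any
    ``builder(dict_of_seqs) -> dendropy.Tree``), find maximal single-species
    clades, and within each clade keep the lexicographically smallest id *per
    group label present* (so no (species, group) combination ever loses its
    last representative).  Halts when no such clade remains, when fewer than
    three sequences survive, or after ``max_rounds`` (defaults to the input
    size, a non-termination guard).

    Returns ``(kept_ids, log)`` where log rows are
    (round, removed_id, representative_id).
    """
    current = dict(seqs.items()) if isinstance(seqs, dict) else dict(seqs)
    if len(current) < 3:
        raise ValueError("need at least three sequences")
    if max_rounds is None:
        max_rounds = len(current)
    log: list[tuple[int, str, str]] = []
    for round_no in range(1, max_rounds + 1):
        if len(current) < 3:
            break
        if builder is None:
            tree = nj_tree(distance_matrix(current, model=model))
        else:
            tree = builder(current)
        clades = same_species_clades(tree, smap)
        removed_any = False
        for clade in clades:
            by_group: dict[str | None, list[str]] = {}
            for label in sorted(clade):
                by_group.setdefault(smap.group_of(label), []).append(label)
            keep = {members[0] for members in by_group.values()}
            for label in sorted(clade):
                if label not in keep and label in current:
                    rep = by_group[smap.group_of(label)][0]
                    del current[label]
                    log.append((round_no, label, rep))
                    removed_any = True
        if not removed_any:
            break
    return sorted(current), log


# ---------------------------------------------------------------------------
# nearest-paralogue links


@dataclass(frozen=True)
class ParalogueLink:
    gene: str
    nearest: str
    distance: float
    same_chromosome: bool


def nearest_paralogue_links(dm: DistanceMatrix, loci) -> list[ParalogueLink]:
    """For each gene, its closest relative and whether they share a
    chromosome (ties broken lexicographically)."""
    chrom = {rec.id: rec.chrom for rec in loci}
    missing = [i for i in dm.ids if i not in chrom]
    if missing:
        raise KeyError(f"loci missing for: {missing[:5]}")
    links = []
    n = len(dm.ids)
    if n < 2:
        return []
    for a in range(n):
        best = None
        for b in range(n):
            if a == b or not dm.valid[a, b]:
                continue
            key = (dm.values[a, b], dm.ids[b])
            if best is None or key < best:
                best = key
        if best is None:
            continue
        d, nearest = best
        links.append(
            ParalogueLink(
                gene=dm.ids[a],
                nearest=nearest,
                distance=float(d),
                same_chromosome=chrom[dm.ids[a]] == chrom[nearest],
            )
        )
    return links


# ---------------------------------------------------------------------------
# per-domain tree incongruence


def _bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Nontrivial bipartitions as frozensets of the side not containing the
    reference (lexicographically smallest) leaf."""
    labels = sorted(_leaf_labels(tree))
    ref = labels[0]
    all_leaves = frozenset(labels)
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(side)
    return out


def tree_incongruence(tree_a: dendropy.Tree, tree_b: dendropy.Tree):
    """Robinson–Foulds distance and tanglegram pairing on shared leaves.

    Returns ``(shared_leaves, rf_distance, pairing)`` where pairing is a
    DataFrame of each shared gene's position in the two trees' leaf orders.
    """
    la, lb = set(_leaf_labels(tree_a)), set(_leaf_labels(tree_b))
    shared = sorted(la & lb)
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared leaves, have {len(shared)}")
    ta = tree_a.extract_tree_with_taxa_labels(shared)
    tb = tree_b.extract_tree_with_taxa_labels(shared)
    rf = len(_bipartitions(ta) ^ _bipartitions(tb))
    order_a = [x for x in _leaf_labels(ta)]
    order_b = [x for x in _leaf_labels(tb)]
    pairing = pd.DataFrame(
        {
            "gene": shared,
            "pos_a": [order_a.index(g) for g in shared],
            "pos_b": [order_b.index(g) for g in shared],
        }
    )
    return shared, rf, pairing


# ---------------------------------------------------------------------------
# newick I/O


def read_newick(source) -> dendropy.Tree:
    """Read a newick tree from a path or string."""
    text = None
    try:
        with open(source) as fh:
            text = fh.read()
    except (OSError, TypeError):
        text = str(source)
    return dendropy.Tree.get(data=text, schema="newick")


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
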