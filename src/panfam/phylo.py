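"""Distance-based phylogenetics: p-distance matrices, neighbor-joining, and
Newick serialization (backed by dendropy tree objects).

Distances are ``1 - identity`` over a pairwise global alignment -- monotone
with divergence at the scales the package works at, with no rate correction.
NJ is the classical Saitou-Nei agglomeration on the Q criterion; it is
consistent on additive matrices, which is what the tests exercise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

from .align import ScoringScheme, global_align, protein_default

__all__ = [
    "DistanceMatrix",
    "distance_matrix",
    "nj",
    "newick_write",
    "newick_read",
    "leaf_distances",
    "is_monophyletic",
]


@dataclass
class DistanceMatrix:
    labels: List[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.labels)]
        for i, lab in enumerate(self.labels):
            lines.append(lab + "\t" + "\t".join(f"{x:.6f}" for x in self.values[i]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "DistanceMatrix":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        labels = lines[0].split("\t")[1:]
        rows = [[float(x) for x in ln.split("\t")[1:]] for ln in lines[1:]]
        return cls(labels, np.array(rows))


def distance_matrix(
    proteins: Mapping[str, str],
    scheme: Optional[ScoringScheme] = None,
) -> DistanceMatrix:
    """Pairwise global-alignment p-distances (1 - identity)."""
    if len(proteins) < 2:
        raise ValueError("need >= 2 sequences")
    if any(not s for s in proteins.values()):
        raise ValueError("empty sequence")
    scheme = scheme or protein_default()
    labels = list(proteins)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(proteins[labels[i]], proteins[labels[j]], scheme)
            d[i, j] = d[j, i] = 1.0 - aln.identity
    return DistanceMatrix(labels, d)


def nj(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining on the Q criterion.

    Negative estimated branch lengths are clamped to 0; ties in Q are broken
    by the smallest (i, j) index pair.  Returns an unrooted dendropy tree
    (trifurcating seed node for n >= 3).
    """
    n = dm.n
    if n < 2:
        raise ValueError("need >= 2 taxa")
    taxa = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: List[dendropy.Node] = []
    for label in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    if n == 2:
        d = float(dm.values[0, 1])
        tree.seed_node.add_child(nodes[0])
        tree.seed_node.add_child(nodes[1])
        nodes[0].edge.length = d / 2
        nodes[1].edge.length = d / 2
        return tree

    D = dm.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        best: Optional[Tuple[float, int, int]] = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - totals[ai] - totals[aj]
                if best is None or q < best[0] - 1e-12:
                    best = (q, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        delta = (totals[ai] - totals[aj]) / (m - 2)
        li = max(0.0, 0.5 * (dij + delta))
        lj = max(0.0, 0.5 * (dij - delta))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        # New distances to the joined node (stored in row/col i).
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            dk = 0.5 * (sub[ai, ak] + sub[aj, ak] - dij)
            D[i, k] = D[k, i] = max(0.0, dk)
        nodes[i] = parent
        active.remove(j)

    # Join the final three nodes at the unrooted seed.
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = max(0.0, 0.5 * (dab + dac - dbc))
    lb = max(0.0, 0.5 * (dab + dbc - dac))
    lc = max(0.0, 0.5 * (dac + dbc - dab))
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        tree.seed_node.add_child(node)
        node.edge.length = length
    tree.is_rooted = False
    return tree


def newick_write(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"


def newick_read(text: str) -> dendropy.Tree:
    """Parse Newick; malformed input raises ValueError carrying the parser's
    position information."""
    try:
        return dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"Newick parse error: {exc}") from exc


def leaf_distances(tree: dendropy.Tree) -> Dict[Tuple[str, str], float]:
    """Patristic distances between all leaf pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    out: Dict[Tuple[str, str], float] = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            key = tuple(sorted((t1.label, t2.label)))
            out[key] = pdm.patristic_distance(t1, t2)
    return out


def is_monophyletic(tree: dendropy.Tree, labels: Set[str]) -> bool:
    """True iff ``labels`` form a clade on some rooting of the (unrooted)
    tree, i.e. the leaf bipartition labels-vs-rest exists as an edge."""
    all_labels = {t.label for t in tree.taxon_namespace}
    if not labels or labels == all_labels:
        return True
    target = frozenset(labels)
    complement = frozenset(all_labels - labels)
    tree.encode_bipartitions()
    for edge in tree.preorder_edge_iter():
        if edge.bipartition is None:
            continue
        side = frozenset(
            t.label for t in edge.bipartition.leafset_taxa(tree.taxon_namespace)
        )
        if side == target or side == complement:
            return True
    return False
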