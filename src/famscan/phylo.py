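"""Domain alignment, distances, neighbor joining, rooting, and Newick I/O.

The self-contained phylogeny path is: implicit multiple alignment from the
profile-HMM state paths (one column per match state), p-distances over the
comparable columns, a Saitou-Nei neighbor-joining tree with deterministic
lexicographic tie-breaking, and midpoint rooting.  Externally built trees
(e.g. maximum-likelihood trees) can be imported as Newick instead; dendropy
provides the tree structure and Newick serialization underneath.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from famscan.core_seq import SeqRecord
from famscan.profile_hmm import ProfileHMM, DomainHit

logger = logging.getLogger(__name__)

GAP = "-"


class TreeError(ValueError):
    """Raised for malformed trees, matrices, or Newick input."""


@dataclass
class PhyloTree:
    """A phylogenetic tree with leaf labels and non-negative branch lengths."""

    dtree: dendropy.Tree
    rooted: bool = False

    def leaf_labels(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self.dtree.leaf_node_iter())

    def n_leaves(self) -> int:
        return sum(1 for _ in self.dtree.leaf_node_iter())

    def clone(self) -> "PhyloTree":
        return PhyloTree(dtree=self.dtree.clone(depth=1), rooted=self.rooted)

    def __post_init__(self) -> None:
        labels = [lf.taxon.label for lf in self.dtree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise TreeError("leaf labels must be unique")
        for edge in self.dtree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                # float-epsilon negatives from midpoint arithmetic clamp to 0
                if edge.length > -1e-9:
                    edge.length = 0.0
                else:
                    raise TreeError("branch lengths must be non-negative")


# ---------------------------------------------------------------------------
# Implicit MSA from HMM paths


def implicit_msa(hmm: ProfileHMM, hits: Sequence[DomainHit],
                 sequences: Mapping[str, str]) -> list[SeqRecord]:
    """Align hits by their profile state paths: one column per match state.

    Match-emitted residues go to their state's column, deleted states become
    gaps, insert-emitted residues are dropped.  ``sequences`` maps target ids
    to the protein strings that were scanned.
    """
    rows: list[SeqRecord] = []
    for hit in hits:
        if hit.path is None:
            raise TreeError(f"hit {hit.target_id} has no alignment path")
        row = [GAP] * hmm.K
        m = hit.matched_states[0]
        i = hit.target_start
        seq = sequences[hit.target_id]
        for state in hit.path:
            if state == "M":
                row[m] = seq[i]
                m += 1
                i += 1
            elif state == "D":
                row[m] = GAP
                m += 1
            else:  # insert: residue dropped from the alignment
                i += 1
        rows.append(SeqRecord(id=hit.target_id, residues="".join(row),
                              alphabet="protein"))
    return rows


def p_distance_matrix(msa: Sequence[SeqRecord]) -> tuple[np.ndarray, list[str]]:
    """Pairwise p-distances (mismatches / comparable columns, gaps excluded)."""
    if len(msa) < 2:
        raise TreeError("p-distance needs at least 2 rows")
    labels = [r.id for r in msa]
    arr = np.array([list(r.residues) for r in msa])
    n = len(msa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arr[i] != GAP) & (arr[j] != GAP)
            ncomp = int(ok.sum())
            if ncomp == 0:
                raise TreeError(f"no comparable columns between {labels[i]!r} "
                                f"and {labels[j]!r}")
            d = float((arr[i][ok] != arr[j][ok]).sum()) / ncomp
            D[i, j] = D[j, i] = d
    return D, labels


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(distances: np.ndarray, labels: Sequence[str]) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing the Q-criterion is joined; ties are
    broken by the lexicographically smallest (sorted) label pair, where an
    internal node carries the smallest leaf label beneath it.  Negative branch
    length estimates are clamped to zero with the deficit moved to the sibling
    branch.  The result is unrooted (trifurcating central node).
    """
    D = np.asarray(distances, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise TreeError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T, atol=1e-12):
        raise TreeError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(D)) > 1e-12):
        raise TreeError("distance matrix must have zero diagonal")
    if n < 2:
        raise TreeError("need at least 2 taxa")

    # Canonical label order makes the join sequence (and float summation
    # order) independent of the input permutation.
    order = sorted(range(n), key=lambda i: labels[i])
    labels_c = [labels[i] for i in order]
    D = D[np.ix_(order, order)].copy()

    taxa = dendropy.TaxonNamespace(labels_c)
    nodes: list[dendropy.Node] = []
    for lab in labels_c:
        nodes.append(dendropy.Node(taxon=taxa.get_taxon(lab)))
    keys = list(labels_c)  # smallest leaf label under each active node
    active = list(range(n))

    def join(i: int, j: int, li: float, lj: float) -> int:
        # clamp negative estimates to 0, moving the deficit to the sibling;
        # if the pair's total is itself negative both collapse to 0
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li = max(li + lj, 0.0)
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        return len(nodes) - 1

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                pair_key = tuple(sorted((keys[active[a]], keys[active[b]])))
                cand = (q, pair_key, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _q, _pk, a, b = best
        i, j = active[a], active[b]
        d_ij = sub[a, b]
        li = 0.5 * d_ij + (r[a] - r[b]) / (2 * (m - 2))
        lj = d_ij - li
        u = join(i, j, li, lj)
        new_d = {}
        for c in range(m):
            if c in (a, b):
                continue
            k = active[c]
            new_d[k] = 0.5 * (sub[a, c] + sub[b, c] - d_ij)
        D = np.pad(D, ((0, 1), (0, 1)))
        for k, v in new_d.items():
            D[u, k] = D[k, u] = v
        active = [k for k in active if k not in (i, j)] + [u]

    tree = dendropy.Tree(taxon_namespace=taxa)
    if len(active) == 3:
        i, j, k = active
        d_ij, d_ik, d_jk = D[i, j], D[i, k], D[j, k]
        parts = ((i, 0.5 * (d_ij + d_ik - d_jk)),
                 (j, 0.5 * (d_ij + d_jk - d_ik)),
                 (k, 0.5 * (d_ik + d_jk - d_ij)))
        for idx, ln in parts:
            tree.seed_node.add_child(nodes[idx])
            nodes[idx].edge.length = max(ln, 0.0)
    else:  # len(active) == 2
        i, j = active
        for idx, ln in ((i, D[i, j] / 2), (j, D[i, j] / 2)):
            tree.seed_node.add_child(nodes[idx])
            nodes[idx].edge.length = ln
    tree.is_rooted = False
    _canonical_child_order(tree)
    return PhyloTree(dtree=tree, rooted=False)


# ---------------------------------------------------------------------------
# Midpoint rooting


def _canonical_child_order(dt: dendropy.Tree) -> None:
    """Sort every node's children by smallest descendant leaf label, so that
    logically identical trees serialize identically."""
    min_leaf: dict[int, str] = {}
    for node in dt.postorder_node_iter():
        if node.is_leaf():
            min_leaf[id(node)] = node.taxon.label
        else:
            kids = sorted(node.child_nodes(), key=lambda c: min_leaf[id(c)])
            node.set_child_nodes(kids)
            min_leaf[id(node)] = min_leaf[id(kids[0])]


def _leaf_distances(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = sorted((t for t in tree.taxon_namespace), key=lambda t: t.label)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            out[(t1.label, t2.label)] = pdm.patristic_distance(t1, t2)
    return out


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties between equally long paths are broken by the smallest (sorted) label
    pair.  If all branch lengths are zero the root is placed on the edge above
    the lexicographically smallest leaf, with a logged warning.
    """
    work = tree.clone()
    dt = work.dtree
    leaves = list(dt.leaf_node_iter())
    if len(leaves) < 2:
        raise TreeError("midpoint rooting needs at least 2 leaves")
    for edge in dt.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    dists = _leaf_distances(dt)
    dmax = max(dists.values())
    if dmax == 0:
        lab = min(lf.taxon.label for lf in leaves)
        logger.warning("all branch lengths zero; rooting above leaf %r", lab)
        node = next(lf for lf in dt.leaf_node_iter() if lf.taxon.label == lab)
        dt.reroot_at_edge(node.edge, length1=0.0, length2=0.0,
                          update_bipartitions=False)
        dt.is_rooted = True
        _canonical_child_order(dt)
        return PhyloTree(dtree=dt, rooted=True)
    pair = min(p for p, v in dists.items() if v == dmax)
    by_label = {lf.taxon.label: lf for lf in leaves}
    a, b = by_label[pair[0]], by_label[pair[1]]

    seed = dt.seed_node

    def path_to_root(node):
        out = [node]
        while out[-1] is not seed:
            out.append(out[-1].parent_node)
        return out

    pa, pb = path_to_root(a), path_to_root(b)
    sb = {id(x) for x in pb}
    mrca = next(x for x in pa if id(x) in sb)
    path = pa[:pa.index(mrca)] + [mrca] + \
        list(reversed(pb[:pb.index(mrca)]))

    half = dmax / 2.0
    cum = 0.0
    for k in range(len(path) - 1):
        u, v = path[k], path[k + 1]
        child = u if u.parent_node is v else v  # the edge belongs to the child
        elen = child.edge.length
        if cum + elen >= half and elen > 0:
            into = half - cum  # distance from u along this edge toward v
            # dendropy's reroot_at_edge: length1 goes to the edge's tail
            # (parent) side, length2 to the head (child) side.
            if child is v:
                l_head = elen - into
            else:
                l_head = into
            dt.reroot_at_edge(child.edge, length1=elen - l_head, length2=l_head,
                              update_bipartitions=False)
            break
        cum += elen
    dt.is_rooted = True
    _canonical_child_order(dt)
    return PhyloTree(dtree=dt, rooted=True)


# ---------------------------------------------------------------------------
# Newick I/O


def read_newick(path: str | Path) -> PhyloTree:
    """Read a Newick tree file (quoted labels supported)."""
    try:
        dt = dendropy.Tree.get(path=str(path), schema="newick",
                               preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse-error types
        raise TreeError(f"Newick parse error in {path}: {exc}") from exc
    rooted = bool(dt.is_rooted) or len(dt.seed_node.child_nodes()) == 2
    return PhyloTree(dtree=dt, rooted=rooted)


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string."""
    try:
        dt = dendropy.Tree.get(data=text, schema="newick",
                               preserve_underscores=True)
    except Exception as exc:
        raise TreeError(f"Newick parse error: {exc}") from exc
    rooted = bool(dt.is_rooted) or len(dt.seed_node.child_nodes()) == 2
    return PhyloTree(dtree=dt, rooted=rooted)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(newick_string(tree))


def newick_string(tree: PhyloTree) -> str:
    return tree.dtree.as_string(schema="newick", suppress_rooting=False,
                                unquoted_underscores=True)


def write_distance_tsv(D: np.ndarray, labels: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(labels) + "\n")
        for i, lab in enumerate(labels):
            fh.write(lab + "\t" + "\t".join(f"{x:.6f}" for x in D[i]) + "\n")
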