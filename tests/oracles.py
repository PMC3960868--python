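"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming and tree-traversal
code paths: scores come from explicit enumeration of every legal alignment
path, and tree statistics from exhaustive traversal of every internal node.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np


def enumerate_alignment_scores(hmm, protein: str) -> list[float]:
    """Bit scores of every legal single-domain local alignment path.

    A path enters at any match state a on any residue i0 (cost log2(1/K)),
    proceeds by match/insert/delete moves, and exits freely from any match
    state.  Insert emissions score 0 bits (background); match emissions score
    log2(e/bg); transitions score log2(t).
    """
    idx = hmm.encode(protein)
    em = hmm._em_lo
    t = hmm._log_t
    K, L = hmm.K, len(idx)
    entry = -math.log2(K)
    scores: list[float] = []

    def extend(m: int, i: int, s: float) -> None:
        scores.append(s)  # free exit at match state m
        if m + 1 < K and i + 1 < L:
            extend(m + 1, i + 1, s + t["mm"][m] + em[m + 1, idx[i + 1]])
        # insert runs of length k >= 1 between match m and m+1
        if m + 1 < K:
            k = 1
            while i + k + 1 < L:
                s_ins = s + t["mi"][m] + (k - 1) * t["ii"][m] + t["im"][m]
                extend(m + 1, i + k + 1, s_ins + em[m + 1, idx[i + k + 1]])
                k += 1
        # delete chains D_{m+1}..D_{m+j} then match m+j+1
        if i + 1 < L:
            s_del = s
            for j in range(1, K - m - 1):
                if j == 1:
                    s_del = s + t["md"][m]
                else:
                    s_del = s_del + t["dd"][m + j - 1]
                nxt = m + j + 1
                if nxt < K:
                    extend(nxt, i + 1, s_del + t["dm"][m + j] + em[nxt, idx[i + 1]])

    for i0 in range(L):
        for a in range(K):
            extend(a, i0, entry + em[a, idx[i0]])
    return scores


def oracle_viterbi(hmm, protein: str) -> float:
    return max(enumerate_alignment_scores(hmm, protein))


def oracle_forward(hmm, protein: str) -> float:
    scores = enumerate_alignment_scores(hmm, protein)
    m = max(scores)
    return m + math.log2(sum(2.0 ** (s - m) for s in scores))


# ---------------------------------------------------------------------------
# Tree oracles


def oracle_monospecific_nodes(tree, species_map, focal_species) -> int:
    """Count internal nodes whose descendant leaves all belong to one species,
    by scanning every internal node's full leaf set independently."""
    count = 0
    for node in tree.dtree.preorder_node_iter():
        if node.is_leaf():
            continue
        species = {species_map[lf.taxon.label] for lf in node.leaf_iter()}
        if species == {focal_species}:
            count += 1
    return count


def oracle_maximal_monospecific_clades(tree, species_map):
    """Enumerate maximal single-species clades by brute-force subset checks."""
    clades = []
    for node in tree.dtree.preorder_node_iter():
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        species = {species_map[l] for l in leaves}
        if len(species) != 1:
            continue
        parent = node.parent_node
        if parent is not None:
            pspecies = {species_map[lf.taxon.label] for lf in parent.leaf_iter()}
            if len(pspecies) == 1:
                continue  # not maximal
        clades.append((next(iter(species)), frozenset(leaves)))
    return clades


def tree_path_distances(newick_tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths computed by explicit root-path subtraction."""
    import dendropy

    pdm = newick_tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(newick_tree.taxon_namespace)
    for t1, t2 in product(taxa, taxa):
        out[(t1.label, t2.label)] = pdm.patristic_distance(t1, t2)
    return out


def random_additive_instance(n, rng, min_len=0.1, max_len=1.0):
    """A random binary tree as (labels, distance dict, newick string).

    Distances are computed by explicit accumulation during construction, so
    the matrix is additive by construction and independent of any tree code.
    """
    labels = [f"t{i:02d}" for i in range(n)]
    items = [({lab: 0.0}, lab) for lab in labels]
    D: dict[tuple[str, str], float] = {}
    while len(items) > 1:
        j = int(rng.integers(1, len(items)))
        i = int(rng.integers(0, j))
        dj, nj = items.pop(j)
        di, ni = items.pop(i)
        li = float(rng.uniform(min_len, max_len))
        lj = float(rng.uniform(min_len, max_len))
        for a, da in di.items():
            for b, db in dj.items():
                D[(a, b)] = D[(b, a)] = da + li + db + lj
        merged = {a: d + li for a, d in di.items()}
        merged.update({b: d + lj for b, d in dj.items()})
        items.append((merged, f"({ni}:{li:.10f},{nj}:{lj:.10f})"))
    newick = items[0][1] + ";"
    return labels, D, newick


def random_species_tree(n_leaves, n_species, rng):
    """A random rooted binary tree over leaves labeled with random species;
    returns (newick, species_map)."""
    labels = [f"g{i:03d}" for i in range(n_leaves)]
    species_map = {lab: f"sp{int(rng.integers(n_species))}" for lab in labels}
    items = list(labels)
    while len(items) > 1:
        j = int(rng.integers(1, len(items)))
        i = int(rng.integers(0, j))
        b = items.pop(j)
        a = items.pop(i)
        items.append(f"({a}:1,{b}:1)")
    return items[0] + ";", species_map
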