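"""Duplication-pattern statistics on a labeled gene tree with gene coordinates.

Three summaries of a family's expansion history:

* maximal species-specific clades (clades whose leaves all come from one
  species and whose parent clade does not) and their size histogram;
* lineage-specific duplication counts — internal nodes whose descendant
  leaves all belong to the focal species, which for binary trees equals
  the sum of (clade size - 1) over that species' maximal clades;
* positional classes of duplicate pairs: sibling leaf pairs (cherries) in a
  monospecific clade are tandem when adjacent in gene order on the same
  chromosome, proximal when separated by at most a configurable number of
  gene ranks (default 10), and distal otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from famscan.phylo import PhyloTree

logger = logging.getLogger(__name__)

DEFAULT_PROXIMAL_MAX_GAP = 10
DEFAULT_SIZE_BINS = (10, 9, 8, 7, 6, 5)


class DupStatsError(ValueError):
    pass


@dataclass(frozen=True)
class SpeciesClade:
    species: str
    leaves: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.leaves)


@dataclass
class GenePosition:
    """Chromosomal position and gene-order rank of one gene."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    rank: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise DupStatsError(f"gene {self.gene_id}: start must be < end")


def positions_from_table(rows: Sequence[tuple[str, str, int, int]]) -> dict[str, GenePosition]:
    """Build positions with ranks computed from coordinate order per chromosome.

    ``rows`` are (gene_id, chromosome, start, end) over the *full* gene
    complement; the rank of a gene is its 0-based order along its chromosome.
    """
    by_chrom: dict[str, list[tuple[str, str, int, int]]] = {}
    for row in rows:
        by_chrom.setdefault(row[1], []).append(row)
    out: dict[str, GenePosition] = {}
    for chrom, items in by_chrom.items():
        items.sort(key=lambda r: (r[2], r[3], r[0]))
        for rank, (gid, _c, s, e) in enumerate(items):
            if gid in out:
                raise DupStatsError(f"duplicate gene id {gid!r} in position table")
            out[gid] = GenePosition(gid, chrom, s, e, rank)
    return out


def read_positions_tsv(path: str | Path) -> dict[str, GenePosition]:
    """TSV with header gene_id, chromosome, start, end [, rank].

    If a rank column is present it is used directly; otherwise ranks are
    computed from coordinate order.
    """
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    has_rank = "rank" in header
    rows = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        parts = ln.split("\t")
        rows.append(parts)
    if has_rank:
        out = {}
        for parts in rows:
            gid, chrom, s, e, rank = parts[:5]
            out[gid] = GenePosition(gid, chrom, int(s), int(e), int(rank))
        return out
    return positions_from_table([(p[0], p[1], int(p[2]), int(p[3])) for p in rows])


# ---------------------------------------------------------------------------
# Clade enumeration


def _leafsets_and_species(tree: PhyloTree, species_map: Mapping[str, str]):
    dt = tree.dtree
    for lf in dt.leaf_node_iter():
        if lf.taxon.label not in species_map:
            raise DupStatsError(f"leaf {lf.taxon.label!r} has no species")
    mono: dict[int, str | None] = {}  # node -> species if monospecific else None
    for node in dt.postorder_node_iter():
        if node.is_leaf():
            mono[id(node)] = species_map[node.taxon.label]
        else:
            sp = {mono[id(ch)] for ch in node.child_nodes()}
            mono[id(node)] = sp.pop() if len(sp) == 1 and None not in sp else None
    return mono


def species_specific_clades(rooted_tree: PhyloTree,
                            species_map: Mapping[str, str]) -> list[SpeciesClade]:
    """All maximal single-species clades (singletons included).

    A clade is maximal when its parent clade is not monospecific (or it is the
    root).  Output is ordered by (species, smallest leaf label).
    """
    dt = rooted_tree.dtree
    mono = _leafsets_and_species(rooted_tree, species_map)
    clades: list[SpeciesClade] = []
    for node in dt.preorder_node_iter():
        sp = mono[id(node)]
        if sp is None:
            continue
        parent = node.parent_node
        if parent is not None and mono[id(parent)] is not None:
            continue
        if node.is_leaf():
            leaves = frozenset([node.taxon.label])
        else:
            leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        clades.append(SpeciesClade(species=sp, leaves=leaves))
    clades.sort(key=lambda c: (c.species, min(c.leaves)))
    return clades


def clade_size_histogram(clades: Sequence[SpeciesClade],
                         bins: Sequence[int] = DEFAULT_SIZE_BINS,
                         ) -> tuple[dict[str, int], dict[int, int]]:
    """Bin clade sizes (default: >=10, 9, 8, 7, 6, 5, plus an "other" bucket).

    Returns (binned counts, full unbinned histogram).
    """
    bins = sorted(bins, reverse=True)
    top = bins[0]
    binned = {f">={top}": 0}
    for b in bins[1:]:
        binned[str(b)] = 0
    binned["other"] = 0
    full: dict[int, int] = {}
    for c in clades:
        full[c.size] = full.get(c.size, 0) + 1
        if c.size >= top:
            binned[f">={top}"] += 1
        elif c.size in bins:
            binned[str(c.size)] += 1
        else:
            binned["other"] += 1
    return binned, full


# ---------------------------------------------------------------------------
# Duplication counts


def _resolved_binary(tree: PhyloTree) -> PhyloTree:
    """Deterministically resolve polytomies (children ordered by smallest
    leaf label, resolved left-to-right); returns a clone if changes needed."""
    if not any(len(nd.child_nodes()) > 2
               for nd in tree.dtree.preorder_node_iter()):
        return tree
    work = tree.clone()
    dt = work.dtree

    def min_leaf(node):
        if node.is_leaf():
            return node.taxon.label
        return min(lf.taxon.label for lf in node.leaf_iter())

    changed = False
    for node in list(dt.postorder_node_iter()):
        kids = node.child_nodes()
        if len(kids) <= 2:
            continue
        changed = True
        kids = sorted(kids, key=min_leaf)
        for k in kids:
            node.remove_child(k)
        left = kids[0]
        for k in kids[1:-1]:
            inner = type(node)()
            inner.add_child(left)
            inner.add_child(k)
            left = inner
        node.add_child(left)
        node.add_child(kids[-1])
    if changed:
        logger.info("resolved polytomies deterministically for duplication counting")
    return work


def lineage_specific_duplications(rooted_tree: PhyloTree,
                                  species_map: Mapping[str, str],
                                  focal_species: str) -> int:
    """Number of internal nodes whose descendant leaves are all focal-species.

    Polytomies are resolved deterministically first, so the count equals the
    sum of (size - 1) over the focal species' maximal monospecific clades.
    """
    if focal_species not in set(species_map.values()):
        raise DupStatsError(f"unknown species {focal_species!r}")
    tree = _resolved_binary(rooted_tree)
    mono = _leafsets_and_species(tree, species_map)
    count = 0
    for node in tree.dtree.preorder_node_iter():
        if not node.is_leaf() and mono[id(node)] == focal_species:
            count += 1
    return count


# ---------------------------------------------------------------------------
# Positional classes


def classify_duplicate_pairs(clades: Sequence[SpeciesClade], tree: PhyloTree,
                             positions: Mapping[str, GenePosition],
                             proximal_max_gap: int = DEFAULT_PROXIMAL_MAX_GAP,
                             all_pairs: bool = False,
                             ) -> list[tuple[tuple[str, str], str]]:
    """Classify duplicate pairs within maximal monospecific clades.

    By default only cherries (sibling leaf pairs) are classified, one class
    per duplication event; ``all_pairs`` switches to every within-clade pair.
    Same chromosome and |rank difference| == 1 -> tandem; 2..proximal_max_gap
    -> proximal; anything else (including different chromosomes) -> distal.
    """
    for clade in clades:
        for g in clade.leaves:
            if g not in positions:
                raise DupStatsError(f"gene {g!r} missing from the position table")
    dt = tree.dtree
    pairs: list[tuple[str, str]] = []
    if all_pairs:
        for clade in clades:
            leaves = sorted(clade.leaves)
            for i, g1 in enumerate(leaves):
                for g2 in leaves[i + 1:]:
                    pairs.append((g1, g2))
    else:
        clade_lookup = {}
        for clade in clades:
            for g in clade.leaves:
                clade_lookup[g] = clade
        seen = set()
        for node in dt.preorder_node_iter():
            kids = node.child_nodes()
            if len(kids) == 2 and all(k.is_leaf() for k in kids):
                g1, g2 = sorted(k.taxon.label for k in kids)
                c1 = clade_lookup.get(g1)
                if c1 is not None and c1 is clade_lookup.get(g2) and c1.size >= 2 \
                        and (g1, g2) not in seen:
                    pairs.append((g1, g2))
                    seen.add((g1, g2))
        pairs.sort()

    out = []
    for g1, g2 in pairs:
        p1, p2 = positions[g1], positions[g2]
        if p1.chromosome != p2.chromosome:
            cls = "distal"
        else:
            gap = abs(p1.rank - p2.rank)
            if gap == 1:
                cls = "tandem"
            elif 2 <= gap <= proximal_max_gap:
                cls = "proximal"
            else:
                cls = "distal"
        out.append(((g1, g2), cls))
    return out


# ---------------------------------------------------------------------------
# Report


@dataclass
class DuplicationReport:
    """Bundle of the three duplication summaries for one labeled tree."""

    clades: list[SpeciesClade]
    binned_histogram: dict[str, int]
    full_histogram: dict[int, int]
    duplications_per_species: dict[str, int]
    pair_classes: list[tuple[tuple[str, str], str]]

    def summary_text(self) -> str:
        lines = ["Species-specific group sizes:"]
        for key, n in self.binned_histogram.items():
            lines.append(f"  size {key}: {n}")
        lines.append("Lineage-specific duplications:")
        for sp in sorted(self.duplications_per_species):
            lines.append(f"  {sp}: {self.duplications_per_species[sp]}")
        counts = {"tandem": 0, "proximal": 0, "distal": 0}
        for _pair, cls in self.pair_classes:
            counts[cls] += 1
        lines.append(
            f"Duplicate pair classes: {counts['tandem']} tandem, "
            f"{counts['proximal']} proximal, {counts['distal']} distal")
        return "\n".join(lines) + "\n"

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("section\tkey\tvalue\n")
            for c in self.clades:
                fh.write(f"clade\t{c.species}\t{','.join(sorted(c.leaves))}\n")
            for key, n in self.binned_histogram.items():
                fh.write(f"histogram\t{key}\t{n}\n")
            for sp in sorted(self.duplications_per_species):
                fh.write(f"duplications\t{sp}\t{self.duplications_per_species[sp]}\n")
            for (g1, g2), cls in self.pair_classes:
                fh.write(f"pair\t{g1},{g2}\t{cls}\n")


def duplication_report(rooted_tree: PhyloTree, species_map: Mapping[str, str],
                       positions: Mapping[str, GenePosition] | None = None,
                       proximal_max_gap: int = DEFAULT_PROXIMAL_MAX_GAP,
                       ) -> DuplicationReport:
    """Compute all duplication statistics for one labeled tree."""
    clades = species_specific_clades(rooted_tree, species_map)
    binned, full = clade_size_histogram(clades)
    dups = {sp: lineage_specific_duplications(rooted_tree, species_map, sp)
            for sp in sorted(set(species_map.values()))}
    pair_classes = []
    if positions is not None:
        # only clades with full positional coverage are classifiable (gene
        # coordinates typically exist for the focal genome only)
        covered = [c for c in clades if all(g in positions for g in c.leaves)]
        if len(covered) < len(clades):
            logger.info("pair classes: %d/%d clades lack positions, skipped",
                        len(clades) - len(covered), len(clades))
        pair_classes = classify_duplicate_pairs(
            covered, _resolved_binary(rooted_tree), positions, proximal_max_gap)
    return DuplicationReport(
        clades=clades,
        binned_histogram=binned,
        full_histogram=full,
        duplications_per_species=dups,
        pair_classes=pair_classes,
    )
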