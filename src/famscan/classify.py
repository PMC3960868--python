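"""Reference-anchored classification of family members into types and groups.

Unlabeled genes are assigned labels from their position in a rooted gene tree
relative to reference genes of known type (Type I / Type II) and group (Malpha,
Mbeta, Mgamma, MIKC*, MIKCc, or any user-defined vocabulary): ascending from a
query leaf toward the root, the first ancestor whose clade contains at least
one reference decides the call — unanimously labeled references assign their
label, mixed references yield "unclassified".  Classification runs in two
stages: a joint tree with type references fixes the type of every gene, then
per-type trees with group references fix the groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from famscan.core_seq import SeqRecord
from famscan.phylo import (
    PhyloTree, implicit_msa, p_distance_matrix, nj_tree, midpoint_root, TreeError,
)
from famscan.profile_hmm import ProfileHMM, scan_proteins

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"


class ClassifyError(ValueError):
    pass


@dataclass
class ReferenceLabels:
    """Known labels: gene id -> (species, type label, optional group label)."""

    species: dict[str, str] = field(default_factory=dict)
    type_label: dict[str, str] = field(default_factory=dict)
    group_label: dict[str, str | None] = field(default_factory=dict)

    def add(self, gene_id: str, species: str, type_label: str,
            group_label: str | None = None) -> None:
        self.species[gene_id] = species
        self.type_label[gene_id] = type_label
        self.group_label[gene_id] = group_label

    def ids(self) -> list[str]:
        return sorted(self.type_label)

    def __len__(self) -> int:
        return len(self.type_label)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceLabels":
        """Read a TSV with columns gene_id, species, type, group ('' = none)."""
        refs = cls()
        lines = Path(path).read_text().splitlines()
        if not lines:
            raise ClassifyError(f"empty reference table {path}")
        header = lines[0].rstrip("\n").split("\t")
        if header[:2] != ["gene_id", "species"]:
            raise ClassifyError("reference table must start with gene_id, species columns")
        for ln in lines[1:]:
            if not ln.strip():
                continue
            parts = ln.rstrip("\n").split("\t")
            gid, sp, ty = parts[0], parts[1], parts[2]
            grp = parts[3] if len(parts) > 3 and parts[3] else None
            refs.add(gid, sp, ty, grp)
        if not refs.type_label:
            raise ClassifyError(f"reference table {path} has no data rows")
        return refs

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tspecies\ttype\tgroup\n")
            for gid in self.ids():
                fh.write(f"{gid}\t{self.species[gid]}\t{self.type_label[gid]}\t"
                         f"{self.group_label.get(gid) or ''}\n")


@dataclass
class Assignment:
    label: str
    clade_size: int
    n_references: int


@dataclass
class Classification:
    """Per-gene type and group assignments with supporting clade evidence."""

    type_of: dict[str, Assignment] = field(default_factory=dict)
    group_of: dict[str, Assignment] = field(default_factory=dict)

    def type_label(self, gene_id: str) -> str:
        a = self.type_of.get(gene_id)
        return a.label if a else UNCLASSIFIED

    def group_label(self, gene_id: str) -> str:
        a = self.group_of.get(gene_id)
        return a.label if a else UNCLASSIFIED

    def to_tsv(self, path: str | Path) -> None:
        genes = sorted(set(self.type_of) | set(self.group_of))
        with open(path, "w") as fh:
            fh.write("gene_id\ttype\tgroup\ttype_clade_size\ttype_n_refs\t"
                     "group_clade_size\tgroup_n_refs\n")
            for g in genes:
                t = self.type_of.get(g)
                gr = self.group_of.get(g)
                fh.write("\t".join([
                    g,
                    t.label if t else UNCLASSIFIED,
                    gr.label if gr else UNCLASSIFIED,
                    str(t.clade_size if t else 0), str(t.n_references if t else 0),
                    str(gr.clade_size if gr else 0), str(gr.n_references if gr else 0),
                ]) + "\n")


def assign_labels(rooted_tree: PhyloTree, labels: Mapping[str, str],
                  level: str = "type") -> dict[str, Assignment]:
    """First-informative-ancestor label assignment on a rooted tree.

    ``labels`` maps reference leaf ids to their label.  For every unlabeled
    leaf, ascend toward the root; the first ancestor whose clade contains at
    least one reference assigns its label if all references in the clade
    agree, else "unclassified".  Reference leaves keep their own label.

    The root itself is never informative: a query whose first
    reference-containing ancestor is the root sits outside every
    reference-anchored clade (its position relative to the references carries
    no signal), so it is reported "unclassified" rather than inheriting
    whatever labels happen to dominate the tree.
    """
    if not rooted_tree.rooted:
        raise ClassifyError("classification requires a rooted tree")
    dt = rooted_tree.dtree
    leaf_ids = [lf.taxon.label for lf in dt.leaf_node_iter()]
    refs_in_tree = [l for l in leaf_ids if l in labels]
    if not refs_in_tree:
        raise ClassifyError(f"no reference leaves in tree at level {level!r}")

    # postorder: per node, the reference label set and counts beneath it
    info: dict[int, tuple[set[str], int, int]] = {}  # (labels, n_refs, n_leaves)
    for node in dt.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            if lab in labels:
                info[id(node)] = ({labels[lab]}, 1, 1)
            else:
                info[id(node)] = (set(), 0, 1)
        else:
            labs: set[str] = set()
            n_refs = n_leaves = 0
            for ch in node.child_nodes():
                l, r, n = info[id(ch)]
                labs |= l
                n_refs += r
                n_leaves += n
            info[id(node)] = (labs, n_refs, n_leaves)

    out: dict[str, Assignment] = {}
    for lf in dt.leaf_node_iter():
        gid = lf.taxon.label
        if gid in labels:
            out[gid] = Assignment(labels[gid], 1, 1)
            continue
        node = lf.parent_node
        assignment = Assignment(UNCLASSIFIED, 0, 0)
        while node is not None:
            labs, n_refs, n_leaves = info[id(node)]
            if n_refs > 0:
                at_root = node.parent_node is None
                if len(labs) == 1 and not at_root:
                    assignment = Assignment(next(iter(labs)), n_leaves, n_refs)
                else:
                    assignment = Assignment(UNCLASSIFIED, n_leaves, n_refs)
                break
            node = node.parent_node
        out[gid] = assignment
    return out


def build_domain_tree(records: Sequence[SeqRecord], hmm: ProfileHMM,
                      scan_bits: float = float("-inf"),
                      outgroup: Sequence[str] | None = None) -> PhyloTree:
    """Implicit-MSA -> p-distance -> NJ -> rooted tree for a set of proteins.

    Rooting is at the midpoint by default; a non-empty ``outgroup`` id list
    overrides it (root on the outgroup's stem edge).
    """
    hits = scan_proteins(hmm, records, scan_bits)
    seqs = {r.id: r.residues for r in records}
    msa = implicit_msa(hmm, hits, seqs)
    if len(msa) < 3:
        raise ClassifyError("need at least 3 scorable sequences to build a tree")
    D, labels = p_distance_matrix(msa)
    tree = nj_tree(D, labels)
    if outgroup:
        dt = tree.dtree
        og = [lf for lf in dt.leaf_node_iter() if lf.taxon.label in set(outgroup)]
        if not og:
            raise ClassifyError("no outgroup leaves present in tree")
        node = dt.mrca(taxa=[lf.taxon for lf in og]) if len(og) > 1 else og[0]
        edge = node.edge
        elen = edge.length or 0.0
        dt.reroot_at_edge(edge, length1=elen / 2, length2=elen / 2,
                          update_bipartitions=False)
        dt.is_rooted = True
        return PhyloTree(dtree=dt, rooted=True)
    return midpoint_root(tree)


def two_stage_classify(records: Sequence[SeqRecord], hmm: ProfileHMM,
                       refs: ReferenceLabels,
                       scan_bits: float = float("-inf"),
                       outgroup: Sequence[str] | None = None,
                       ) -> tuple[Classification, dict[str, PhyloTree]]:
    """Joint-tree typing followed by per-type group classification.

    Stage 1 builds one tree of all genes plus type references and assigns
    types; stage 2 rebuilds separate trees per type (that type's genes plus
    its references) and assigns group labels.  Genes unclassified at stage 1
    are excluded from stage 2.  Returns the classification and the trees
    (keyed "joint" plus one entry per type label).
    """
    if not refs.type_label:
        raise ClassifyError("empty reference set")
    joint = build_domain_tree(records, hmm, scan_bits, outgroup)
    cls = Classification()
    cls.type_of = dict(assign_labels(joint, refs.type_label, "type"))
    trees: dict[str, PhyloTree] = {"joint": joint}

    by_id = {r.id: r for r in records}
    for ty in sorted(set(refs.type_label.values())):
        members = sorted(
            g for g, a in cls.type_of.items() if a.label == ty and g in by_id
        )
        group_refs = {g: lab for g, lab in refs.group_label.items()
                      if lab is not None and refs.type_label.get(g) == ty}
        subset = [by_id[g] for g in members]
        if len(subset) < 3:
            logger.warning("type %s has %d members; skipping group stage",
                           ty, len(subset))
            continue
        try:
            subtree = build_domain_tree(subset, hmm, scan_bits, outgroup)
        except (ClassifyError, TreeError) as exc:
            logger.warning("group stage failed for type %s: %s", ty, exc)
            continue
        trees[ty] = subtree
        if not any(g in group_refs for g in members):
            logger.warning("no group references among type %s members", ty)
            continue
        for g, a in assign_labels(subtree, group_refs, "group").items():
            cls.group_of[g] = a

    n_untyped = sum(1 for a in cls.type_of.values() if a.label == UNCLASSIFIED)
    if n_untyped:
        logger.info("%d genes could not be classified into a type", n_untyped)
    return cls, trees
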