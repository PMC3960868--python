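"""Seeded synthetic fixtures: seed alignments, gene families, planted genomes.

The generator emulates the data a family-annotation study consumes — a seed
alignment of domain exemplars, a gene family expanded by lineage-specific
duplications with known type/group structure, and genome assemblies with the
family members planted at positions that realize prescribed tandem / proximal
/ distal duplicate classes — together with a truth manifest, so every pipeline
stage can be tested end to end without downloads.

Everything is reproducible bit-for-bit under a fixed seed.  Substitutions use
a uniform amino-acid replacement model: the generator tests pipeline
mechanics, not evolutionary realism.

Duplication histories are caterpillars: each new copy duplicates from the
most recently created gene of its species/group lineage and is planted
downstream of that parent.  The one cherry of each lineage in the final
genealogy therefore realizes exactly the positional class planned for the
last duplication event, which gives duplication statistics a closed,
manifest-checkable truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from famscan.core_seq import (
    SeqRecord, translate, reverse_complement, write_fasta,
    write_gff3_header, format_gff3_line,
)
from famscan.classify import ReferenceLabels
from famscan.phylo import PhyloTree

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Default label vocabulary: the classic plant family split of two ancient
# types, Type I groups Malpha/Mbeta/Mgamma and Type II groups MIKCstar/MIKCc.
DEFAULT_GROUP_TYPES: dict[str, str] = {
    "Malpha": "TypeI", "Mbeta": "TypeI", "Mgamma": "TypeI",
    "MIKCstar": "TypeII", "MIKCc": "TypeII",
}

# Divergence ladder of the simulated family (substitution probability per
# residue on each branch of the hierarchy).  The emulated domain is strongly
# conserved — real exemplars from all groups of the family remain clearly
# alignable — so types differ more than groups, groups more than species, and
# within-species duplicates diverge at the configurable mutation_rate.
TYPE_DIVERGENCE = 0.15
GROUP_DIVERGENCE = 0.10
SPECIES_DIVERGENCE = 0.04
DEFAULT_MUTATION_RATE = 0.03

# Codon table inverted for reverse translation.
_CODONS_BY_AA: dict[str, list[str]] = {}
from famscan.core_seq import STANDARD_CODE as _CODE  # noqa: E402
for _codon, _aa in sorted(_CODE.items()):
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)

STOP_CODON = "TGA"
UPSTREAM_STOP = "TAA"


class SynthError(ValueError):
    pass


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each residue with probability ``rate`` by a different one."""
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = AMINO_ACIDS.replace(out[i], "")
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """DNA for a protein, drawing uniformly among synonymous codons."""
    codons = []
    for aa in protein:
        opts = _CODONS_BY_AA[aa]
        codons.append(opts[rng.integers(len(opts))])
    return "".join(codons)


# ---------------------------------------------------------------------------
# Seed alignment


def sample_seed_alignment(n_rows: int, length: int = 58, divergence: float = 0.1,
                          seed: int = 0, n_gap_columns: int = 2,
                          ancestor: str | None = None) -> list[SeqRecord]:
    """Simulate an aligned set of domain exemplars.

    A random ancestral domain of ``length`` residues is mutated independently
    per row at the given substitution probability; ``n_gap_columns`` extra
    columns with >=60% gaps are interspersed, which fall below the default
    0.5 match-state threshold of profile construction (so the built profile
    has about ``length`` match states).
    """
    if n_rows < 2:
        raise SynthError("need at least 2 rows")
    if not 1 <= length <= 1000:
        raise SynthError("domain length must be in [1, 1000]")
    rng = np.random.default_rng(seed)
    if ancestor is None:
        ancestor = _random_protein(rng, length)
    elif len(ancestor) != length:
        raise SynthError("ancestor length must equal the requested length")
    rows = [_mutate(ancestor, divergence, rng) for _ in range(n_rows)]
    if n_gap_columns and n_rows >= 2:
        positions = sorted(rng.choice(range(1, length), size=min(n_gap_columns, length - 1),
                                      replace=False), reverse=True)
        n_gapped = max(int(np.ceil(0.6 * n_rows)), (n_rows // 2) + 1)
        for pos in positions:
            gapped = set(rng.choice(n_rows, size=n_gapped, replace=False).tolist())
            for r in range(n_rows):
                if r in gapped:
                    ins = "-"
                else:
                    ins = AMINO_ACIDS[rng.integers(20)]
                rows[r] = rows[r][:pos] + ins + rows[r][pos:]
    return [SeqRecord(id=f"seed{r + 1:02d}", residues=rows[r], alphabet="protein")
            for r in range(n_rows)]


# ---------------------------------------------------------------------------
# Family simulation


@dataclass
class SimGene:
    """One simulated family member with its duplication provenance."""

    gene_id: str
    species: str
    type_label: str
    group_label: str
    domain: str
    protein: str
    domain_offset: int  # residue offset of the domain within the protein
    parent: str | None = None  # parent gene of the duplication, None = founder
    dup_class: str | None = None  # tandem | proximal | distal, None = founder


@dataclass
class FamilySim:
    """A simulated family: genes, the true genealogy, and cherry truth."""

    genes: list[SimGene]
    true_tree: PhyloTree
    # expected positional class of the single final-genealogy cherry of each
    # multi-gene species/group lineage: ((gene1, gene2) sorted, class)
    expected_cherry_classes: list[tuple[tuple[str, str], str]]

    def gene(self, gene_id: str) -> SimGene:
        return next(g for g in self.genes if g.gene_id == gene_id)

    def species_map(self) -> dict[str, str]:
        return {g.gene_id: g.species for g in self.genes}

    def protein_records(self) -> list[SeqRecord]:
        return [SeqRecord(id=g.gene_id, residues=g.protein, alphabet="protein")
                for g in self.genes]

    def reference_labels(self, species: Sequence[str]) -> ReferenceLabels:
        """Truth labels of the given species' genes, for use as references."""
        refs = ReferenceLabels()
        chosen = set(species)
        for g in self.genes:
            if g.species in chosen:
                refs.add(g.gene_id, g.species, g.type_label, g.group_label)
        return refs


def simulate_family(seed_domain: str, n_species: int,
                    genes_per_species: Mapping[str, int],
                    duplication_model: Mapping[str, float] | None = None,
                    mutation_rate: float = DEFAULT_MUTATION_RATE,
                    seed: int = 0,
                    group_types: Mapping[str, str] | None = None,
                    flank_lengths: tuple[int, int] = (20, 40)) -> FamilySim:
    """Evolve a gene family over species, groups, and duplication events.

    ``genes_per_species`` maps group label -> gene count per species (honored
    exactly).  ``duplication_model`` gives tandem/proximal/distal probabilities
    for each duplication event (default 0.2/0.2/0.6).  Every gene's protein is
    the (mutated) domain with random N- and C-terminal flanks; the domain is
    what carries the phylogenetic signal.
    """
    group_types = dict(group_types or DEFAULT_GROUP_TYPES)
    unknown = set(genes_per_species) - set(group_types)
    if unknown:
        raise SynthError(f"groups without a type: {sorted(unknown)}")
    dup_model = dict(duplication_model or
                     {"tandem": 0.2, "proximal": 0.2, "distal": 0.6})
    if abs(sum(dup_model.values()) - 1.0) > 1e-9:
        raise SynthError("duplication probabilities must sum to 1")
    if all(n == 0 for n in genes_per_species.values()) or n_species == 0:
        return FamilySim(genes=[], true_tree=None, expected_cherry_classes=[])

    rng = np.random.default_rng(seed)
    classes = sorted(dup_model)
    probs = np.array([dup_model[c] for c in classes])

    species_names = [f"sp{chr(ord('A') + i)}" for i in range(n_species)]
    types = sorted(set(group_types[g] for g in genes_per_species))
    type_anc = {t: _mutate(seed_domain, TYPE_DIVERGENCE, rng) for t in types}
    group_anc = {g: _mutate(type_anc[group_types[g]], GROUP_DIVERGENCE, rng)
                 for g in sorted(genes_per_species)}

    genes: list[SimGene] = []
    taxa = dendropy.TaxonNamespace()
    type_nodes: dict[str, dendropy.Node] = {}
    root = dendropy.Node()
    for t in types:
        nd = dendropy.Node()
        root.add_child(nd)
        nd.edge.length = 1.0
        type_nodes[t] = nd
    cherry_truth: list[tuple[tuple[str, str], str]] = []

    def new_gene(gid, species, group, domain) -> SimGene:
        nf, cf = flank_lengths
        protein = ("M" + _random_protein(rng, nf - 1) + domain
                   + _random_protein(rng, cf))
        return SimGene(gene_id=gid, species=species,
                       type_label=group_types[group], group_label=group,
                       domain=domain, protein=protein, domain_offset=nf)

    for group in sorted(genes_per_species):
        count = genes_per_species[group]
        if count == 0:
            continue
        gnode = dendropy.Node()
        type_nodes[group_types[group]].add_child(gnode)
        gnode.edge.length = 1.0
        for species in species_names:
            founder_domain = _mutate(group_anc[group], SPECIES_DIVERGENCE, rng)
            gid = f"{species}_{group}_1"
            g = new_gene(gid, species, group, founder_domain)
            g.parent = None
            genes.append(g)
            leaf = dendropy.Node(taxon=taxa.new_taxon(gid))
            gnode.add_child(leaf)
            leaf.edge.length = 1.0
            leaf_of = {gid: leaf}
            prev = g
            last_event = None
            for k in range(2, count + 1):
                child_domain = _mutate(prev.domain, mutation_rate, rng)
                cid = f"{species}_{group}_{k}"
                dup_class = classes[rng.choice(len(classes), p=probs)]
                child = new_gene(cid, species, group, child_domain)
                child.parent = prev.gene_id
                child.dup_class = dup_class
                genes.append(child)
                # genealogy: replace the parent leaf by a (parent, child) node
                pl = leaf_of[prev.gene_id]
                inner = dendropy.Node()
                grand = pl.parent_node
                grand.remove_child(pl)
                grand.add_child(inner)
                inner.edge.length = pl.edge.length
                inner.add_child(pl)
                pl.edge.length = 1.0
                cl = dendropy.Node(taxon=taxa.new_taxon(cid))
                inner.add_child(cl)
                cl.edge.length = 1.0
                leaf_of[cid] = cl
                last_event = (tuple(sorted((prev.gene_id, cid))), dup_class)
                prev = child
            if last_event is not None:
                cherry_truth.append(last_event)

    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.add_child(root)
    root.edge.length = 0.0
    tree.is_rooted = True
    return FamilySim(genes=genes,
                     true_tree=PhyloTree(dtree=tree, rooted=True),
                     expected_cherry_classes=sorted(cherry_truth))


# ---------------------------------------------------------------------------
# Genome planting


@dataclass
class PlantedLocus:
    """A gene (family member or decoy) placed on a contig."""

    gene_id: str
    contig_id: str
    cds_start: int  # stop codon excluded
    cds_end: int
    strand: str
    protein: str
    is_decoy: bool
    withheld: bool = False
    rank: int = 0  # order along the contig over the full complement


@dataclass
class GenomeFixture:
    """Planted assembly plus every file the pipeline consumes, as objects."""

    assembly: list[SeqRecord]
    cds_records: list[SeqRecord]  # annotated genes only (decoys included)
    loci: list[PlantedLocus]
    family: FamilySim | None = None

    def truth_by_id(self) -> dict[str, PlantedLocus]:
        return {l.gene_id: l for l in self.loci}

    def planted(self) -> list[PlantedLocus]:
        return [l for l in self.loci if not l.is_decoy]

    def withheld_ids(self) -> set[str]:
        return {l.gene_id for l in self.loci if l.withheld}

    def position_rows(self) -> list[tuple[str, str, int, int]]:
        return [(l.gene_id, l.contig_id, l.cds_start, l.cds_end)
                for l in self.loci]

    def write_annotation_gff3(self, path) -> None:
        """GFF3 of the annotated (non-withheld) genes: the CDS track."""
        with open(path, "w") as fh:
            write_gff3_header(fh)
            for l in self.loci:
                if l.withheld:
                    continue
                fh.write(format_gff3_line(l.contig_id, "synth", "gene",
                                          l.cds_start, l.cds_end, ".", l.strand, ".",
                                          f"ID={l.gene_id}"))
                fh.write(format_gff3_line(l.contig_id, "synth", "CDS",
                                          l.cds_start, l.cds_end, ".", l.strand, "0",
                                          f"Parent={l.gene_id}"))

    def write_truth_gff3(self, path) -> None:
        with open(path, "w") as fh:
            write_gff3_header(fh)
            for l in self.loci:
                attrs = (f"ID={l.gene_id};decoy={int(l.is_decoy)};"
                         f"withheld={int(l.withheld)};rank={l.rank}")
                fh.write(format_gff3_line(l.contig_id, "synth", "gene",
                                          l.cds_start, l.cds_end, ".", l.strand, ".",
                                          attrs))

    def write_manifest_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tcontig\tcds_start\tcds_end\tstrand\trank\t"
                     "is_decoy\twithheld\tspecies\ttype\tgroup\tparent\tdup_class\n")
            by_id = {g.gene_id: g for g in (self.family.genes if self.family else [])}
            for l in self.loci:
                g = by_id.get(l.gene_id)
                fh.write("\t".join([
                    l.gene_id, l.contig_id, str(l.cds_start), str(l.cds_end),
                    l.strand, str(l.rank), str(int(l.is_decoy)),
                    str(int(l.withheld)),
                    g.species if g else "", g.type_label if g else "",
                    g.group_label if g else "", (g.parent or "") if g else "",
                    (g.dup_class or "") if g else "",
                ]) + "\n")


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def plant_genome(family: FamilySim | None, n_contigs: int, contig_length: int,
                 gc_content: float = 0.4, decoy_gene_count: int = 20,
                 withheld_fraction: float = 0.0, seed: int = 0,
                 proximal_max_gap: int = 10,
                 intergenic_bp: tuple[int, int] = (1500, 3000),
                 species_filter: str | None = None) -> GenomeFixture:
    """Plant a simulated family (plus decoy genes) into random contigs.

    Placement realizes each duplication's positional class: tandem children go
    directly after their parent in gene order, proximal children after 1 to
    ``proximal_max_gap - 1`` intervening decoys, distal children on another
    contig (or far away when only one contig exists).  A ``withheld_fraction``
    of planted genes is left out of the CDS track to exercise the
    genome-track rescue path.  Each gene is planted as an in-frame stop codon
    followed by ATG...ORF...stop, so the naive caller can recover the exact
    planted interval.
    """
    rng = np.random.default_rng(seed)
    genes = list(family.genes) if family else []
    if species_filter is not None:
        genes = [g for g in genes if g.species == species_filter]

    @dataclass
    class Slot:
        gene_id: str
        protein: str
        is_decoy: bool
        strand: str

    contig_slots: list[list[Slot]] = [[] for _ in range(n_contigs)]
    slot_contig: dict[str, int] = {}

    def place_after(contig_idx: int, after_gene: str | None, slot: Slot,
                    n_intervening_decoys: int = 0) -> None:
        lst = contig_slots[contig_idx]
        pos = len(lst)
        if after_gene is not None:
            pos = next(i for i, s in enumerate(lst) if s.gene_id == after_gene) + 1
        fillers = []
        for d in range(n_intervening_decoys):
            did = f"decoy_fill_{slot.gene_id}_{d}"
            fillers.append(Slot(gene_id=did,
                                protein="M" + _random_protein(rng, 99),
                                is_decoy=True,
                                strand="+-"[rng.integers(2)]))
        for f in fillers + [slot]:
            lst.insert(pos, f)
            pos += 1
        slot_contig[slot.gene_id] = contig_idx

    # founders round-robin over contigs; children per their class
    next_contig = 0
    for g in genes:
        strand = "+-"[rng.integers(2)]
        slot = Slot(gene_id=g.gene_id, protein=g.protein,
                    is_decoy=False, strand=strand)
        if g.parent is None:
            place_after(next_contig % n_contigs, None, slot)
            next_contig += 1
        elif g.dup_class == "tandem":
            place_after(slot_contig[g.parent], g.parent, slot, 0)
        elif g.dup_class == "proximal":
            k = int(rng.integers(1, proximal_max_gap))  # rank gap = k + 1
            place_after(slot_contig[g.parent], g.parent, slot, k)
        else:  # distal
            if n_contigs > 1:
                choices = [c for c in range(n_contigs) if c != slot_contig[g.parent]]
                place_after(choices[rng.integers(len(choices))], None, slot)
            else:
                # same contig, guaranteed far: at the list end with enough
                # intervening decoys to exceed the proximal window
                lst = contig_slots[0]
                parent_pos = next(i for i, s in enumerate(lst)
                                  if s.gene_id == g.parent)
                deficit = max(0, proximal_max_gap + 1 - (len(lst) - parent_pos))
                place_after(0, None, slot, deficit)

    # free decoys appended round-robin
    for d in range(decoy_gene_count):
        slot = Slot(gene_id=f"decoy_{d + 1:03d}",
                    protein="M" + _random_protein(rng, 99),
                    is_decoy=True, strand="+-"[rng.integers(2)])
        place_after(d % n_contigs, None, slot)

    # withhold a fraction of planted genes from the CDS track
    planted_ids = [g.gene_id for g in genes]
    n_withheld = int(round(withheld_fraction * len(planted_ids)))
    withheld = set(
        np.array(planted_ids)[rng.choice(len(planted_ids), size=n_withheld,
                                         replace=False)].tolist()
    ) if n_withheld else set()

    # lay the slots onto sequence
    assembly: list[SeqRecord] = []
    loci: list[PlantedLocus] = []
    cds_records: list[SeqRecord] = []
    lo_bp, hi_bp = intergenic_bp
    for ci in range(n_contigs):
        parts: list[str] = []
        pos = 0
        contig_id = f"contig{ci + 1}"
        for rank, slot in enumerate(contig_slots[ci]):
            gap = int(rng.integers(lo_bp, hi_bp))
            parts.append(_random_dna(rng, gap, gc_content))
            pos += gap
            cds = _reverse_translate(slot.protein, rng)
            cds = "ATG" + cds[3:]  # first codon is the start
            gene_dna = UPSTREAM_STOP + cds + STOP_CODON
            if slot.strand == "+":
                cds_start = pos + 3
                cds_end = cds_start + len(cds)
                parts.append(gene_dna)
            else:
                parts.append(reverse_complement(gene_dna))
                cds_start = pos + 3
                cds_end = cds_start + len(cds)
            pos += len(gene_dna)
            loci.append(PlantedLocus(
                gene_id=slot.gene_id, contig_id=contig_id,
                cds_start=cds_start, cds_end=cds_end, strand=slot.strand,
                protein=slot.protein, is_decoy=slot.is_decoy,
                withheld=slot.gene_id in withheld, rank=rank,
            ))
            if slot.gene_id not in withheld:
                # coding-strand CDS, terminal stop excluded
                cds_records.append(SeqRecord(id=slot.gene_id, residues=cds,
                                             alphabet="dna"))
        tail = contig_length - pos
        if tail < 0:
            raise SynthError(
                f"contig {contig_id} too short: needs at least {pos} bp")
        parts.append(_random_dna(rng, tail, gc_content))
        assembly.append(SeqRecord(id=contig_id, residues="".join(parts),
                                  alphabet="dna"))

    fx = GenomeFixture(assembly=assembly, cds_records=cds_records,
                       loci=loci, family=family)
    _verify_planting(fx)
    return fx


def _verify_planting(fx: GenomeFixture) -> None:
    """Assert manifest/emission consistency: every locus CDS translates back
    to its protein.  (The 3-bp flanking stop codons make the interval
    arithmetic identical on both strands.)"""
    contigs = {c.id: c.residues for c in fx.assembly}
    for l in fx.loci:
        seq = contigs[l.contig_id][l.cds_start:l.cds_end]
        if l.strand == "-":
            seq = reverse_complement(seq)
        prot = translate(seq)
        if prot != l.protein:
            raise AssertionError(f"planting inconsistency for {l.gene_id}")


# ---------------------------------------------------------------------------
# Standard fixture


DEFAULT_GENES_PER_GROUP: dict[str, int] = {
    "Malpha": 8, "Mbeta": 6, "Mgamma": 6, "MIKCstar": 4, "MIKCc": 6,
}  # 30 family genes per species


@dataclass
class StudyFixture:
    """The bundled study conditions: seed alignment, family, planted genome."""

    ancestor: str
    seed_alignment: list[SeqRecord]
    family: FamilySim
    genome: GenomeFixture
    focal_species: str


def make_fixture(seed: int = 0, n_species: int = 3,
                 genes_per_group: Mapping[str, int] | None = None,
                 n_contigs: int = 5, contig_length: int = 400_000,
                 decoy_gene_count: int = 30, withheld_fraction: float = 0.3,
                 mutation_rate: float = DEFAULT_MUTATION_RATE,
                 seed_rows: int = 12, domain_length: int = 58,
                 seed_divergence: float = 0.10,
                 duplication_model: Mapping[str, float] | None = None,
                 ) -> StudyFixture:
    """Generate the standard synthetic study: a 5-contig, 2-Mb genome of the
    focal species carrying 30 planted family genes (30% withheld from the CDS
    track), a 12-row seed alignment of the ancestral domain, and a 3-species
    family with known type/group truth for classification."""
    rng = np.random.default_rng(seed)
    ancestor = _random_protein(rng, domain_length)
    seed_msa = sample_seed_alignment(seed_rows, domain_length, seed_divergence,
                                     seed=seed + 1, ancestor=ancestor)
    family = simulate_family(
        ancestor, n_species, dict(genes_per_group or DEFAULT_GENES_PER_GROUP),
        duplication_model=duplication_model,
        mutation_rate=mutation_rate, seed=seed + 2,
    )
    focal = family.genes[0].species if family.genes else "spA"
    genome = plant_genome(
        family, n_contigs=n_contigs, contig_length=contig_length,
        decoy_gene_count=decoy_gene_count, withheld_fraction=withheld_fraction,
        seed=seed + 3, species_filter=focal,
    )
    return StudyFixture(ancestor=ancestor, seed_alignment=seed_msa,
                        family=family, genome=genome, focal_species=focal)
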