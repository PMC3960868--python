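# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of `famscan`, in the order the pipeline runs them.

## Profile HMM

**Architecture.**  The profile is the textbook match/insert/delete chain:
match states `M_1..M_K` with position-specific 20-way emission distributions,
insert states `I_1..I_{K-1}` emitting at the background distribution, and
silent delete states.  Scoring is *single-domain local* log-odds alignment:
a path enters at any match state with uniform probability `1/K`, exits from
any match state at no cost, and residues outside the aligned span are emitted
at background, contributing 0 bits.  Insert emissions at background mean
inserts cost only their transitions.  All scores are in bits (log2).  This
architecture fits domains that occur once per protein — the emulated
DNA-binding domain is 56–60 aa and appears once per family member — and, at
K ≤ 4, every legal alignment path can be enumerated, which is how the Viterbi
and forward implementations are verified (to 1e-9; observed agreement is at
machine precision).

The begin/end transitions are architecture constants, not estimated: uniform
`1/K` entry over match states and free exit.  Estimating local entry/exit
from a seed alignment of full-length domains would drive them toward glocal
alignment and was deliberately avoided; interior transitions *are* estimated
from the seed rows' implied state paths.

**Construction.**  Columns of the seed alignment with gap fraction strictly
below `gap_threshold` (default 0.5) become match states.  Emissions use
background-weighted Laplace pseudocounts, `(n_a + w·q_a)/(n + w)` with weight
`w = 1.0` by default, where the background `q` is the seed-wide residue
frequency smoothed with a uniform pseudocount.  Transitions use the same rule
with a uniform prior over each state's 2 or 3 outgoing edges.  Dirichlet
mixture priors would be the heavier-duty alternative; the single named knob
(`pseudocount_weight`) is simpler and sufficient for seed alignments of a
dozen close exemplars.  A seed row whose insert run is followed by a deletion
(or preceded by one) has no representation in this architecture; such
transitions are counted as the nearest representable event, and the
pseudocounts keep all probabilities positive.

**Scoring.**  The Viterbi and forward recurrences are vectorized over match
states; delete chains are folded into one `maximum.accumulate`
(resp. `logaddexp2.accumulate`) pass per residue, so scanning is O(L·K) with
numpy-level constants.  Paths are reconstructed only for retained hits, with
ties broken Match > Delete > Insert.  Residue `X` scores 0 bits (background);
other non-amino-acid characters are errors.  Scores are reported in bits and
never converted to E-values: the two fixed thresholds below make E-value
calibration unnecessary for this workflow, and multi-hit (J-state)
architecture is out of scope.

**Thresholds.**  Scanning uses a permissive 10-bit threshold; a gene enters
the final set only if its protein re-scores at ≥ 20 bits (`confirm_bits`).
The two-threshold scheme replaces an external conserved-domain-database
confirmation with a second, stricter score check.  On the synthetic study the
margin is wide: planted domains score 90–140 bits while the maximum over
random 100-kb six-frame backgrounds stays near 13–14 bits.

## Six-frame genome scan

Contigs are translated in all six frames with exact coordinate maps
(0-based half-open everywhere internally; GFF3 output converts to 1-based
closed at the boundary).  Frame peptides are split at stop codons and only
stop-free segments of ≥ `min_peptide` = 40 aa are scanned — below the 56-aa
domain so truncated halves remain detectable, but a domain whose genomic copy
is interrupted by an intron containing an in-frame stop is missed, exactly as
in any translated-genome search.  Same-strand overlapping hits from different
frames collapse to the best score (ties: lowest frame offset).  Candidate
loci are extracted 300 bp upstream and 19,700 bp downstream of the detected
domain start; on the minus strand the window mirrors about the
higher-coordinate end of the box, which this toolkit asserts as its contract.
Windows are clipped at contig bounds and flagged.

Soft-masked (lowercase) residues are uppercased and scanned; IUPAC ambiguity
codes beyond N map to N with a logged warning, and codons containing N
translate to X.

## Gene models and the two-track merge

The built-in caller is single-exon by design: from the hit's reading frame it
extends 5' to the nearest in-frame ATG after the nearest upstream in-frame
stop and 3' to the first in-frame stop, requiring ≥ 60 codons (≈ one domain).
If the 5' search exhausts the window without a stop, the model starts at the
window edge and is flagged `partial`; multi-exon recovery is delegated to the
external-predictor interface (any shell command printing GFF3 over the region
FASTA).  CDS intervals exclude the terminal stop codon so that
`translate(CDS) == protein` holds exactly.

Two genome-track/CDS-track models are "the same gene" when they lie on the
same strand and their CDS spans overlap reciprocally by ≥ 0.5 (both
directions); the CDS-track copy wins.  Merged models receive deterministic
ids (configurable prefix + running number in coordinate order), and a QC
table (source track, partial flag, confirmation bits) replaces manual
inspection as the human checkpoint.

## Phylogeny

The alignment of accepted domains is *implicit*: each hit's HMM state path
places match-emitted residues into their state's column (K columns total),
deletions become gaps, insert residues are dropped.  This replaces an
external aligner run and is exactly consistent with the model that scored the
hits; externally aligned FASTA can be substituted.  Distances are
p-distances over columns where neither row is gapped (an error if no column
qualifies).  Trees are Saitou–Nei neighbor joining with two determinism
guarantees: taxa are processed in canonical label order (so input permutation
cannot change float summation order), and Q-criterion ties break by the
lexicographically smallest label pair, internal nodes carrying their smallest
descendant leaf label.  Negative branch-length estimates clamp to zero with
the deficit moved to the sibling; when a pair's total is negative both clamp
to zero.  NJ on additive matrices reproduces the generating tree's full path
metric to 1e-9 (200-tree sweep).  Maximum-likelihood inference is a non-goal;
externally built ML trees import via Newick (dendropy underneath).

Midpoint rooting takes the longest leaf-to-leaf path (ties: smallest label
pair), places the root at its midpoint, and canonically orders children so
rerooting is idempotent and serialization byte-stable.  An all-zero-length
tree roots above the smallest-labeled leaf with a warning.  A user-supplied
outgroup id list overrides midpoint rooting.

## Classification

Stage 1 builds a joint tree of all query proteins plus references and assigns
Type I / Type II; stage 2 rebuilds one tree per assigned type (members plus
that type's group references) and assigns groups.  Genes untyped at stage 1
are excluded from stage 2 and reported.

The assignment rule is first-informative-ancestor: ascend from the query
until a clade contains at least one reference; unanimous references assign
their label, disagreeing references yield "unclassified".  One refinement:
an informative ancestor that is the tree *root* also yields "unclassified".
At the root the query sits outside every reference-anchored clade — its
position carries no signal — and without this rule a query family absent from
the references would inherit whatever label happens to dominate the tree
(verified by the reference-ablation test: removing all Type II references
leaves Type II genes unclassified rather than mislabeled Type I).  The
flip side is that both stages need at least two labeled clades below the
root to be informative, which holds whenever each type carries two or more
groups, as in the emulated family.

## Duplication statistics

Maximal species-specific clades are nodes whose leaves are one species and
whose parent's are not (singletons included), enumerated in deterministic
order and binned into the size histogram (≥10, 9..5, other).
Lineage-specific duplications are counted as internal nodes whose descendant
leaves all belong to the focal species — a total, oracle-checkable
operationalization of "duplications not shared with the sister species" —
and equal Σ(size − 1) over that species' maximal clades once polytomies are
resolved (deterministically: children ordered by smallest leaf label,
left-ladderized).  Both are verified against an exhaustive node-scan oracle
on 200 random labeled trees.

Duplicate pairs are classified positionally from gene-order ranks over the
full gene complement: same chromosome and rank gap 1 → tandem, gap 2–10 →
proximal (`proximal_max_gap`, a named knob), otherwise distal.  By default
only cherries (sibling leaf pairs) are classified — cherries correspond to
individual duplication events — with an all-pairs mode behind a flag.

## Synthetic data generator

The generator emulates the *structure* the pipeline assumes, not
evolutionary realism: substitutions use a uniform replacement model (no
PAM/BLOSUM weighting, no codon-usage or intron modeling), and flanking
protein sequence is random.  Its defaults define the bundled study:

* domain length 58 aa; 12-row seed alignment at divergence 0.10 with two
  majority-gap columns (so profile K lands within ±2 of 58);
* a divergence ladder — type 0.15, group 0.10, species 0.04 substitutions
  per site, within-species duplication events at `mutation_rate` = 0.03 —
  chosen to emulate a strongly conserved domain whose exemplars from all
  groups remain clearly alignable, with types more distinct than groups and
  groups more distinct than species;
* per species: 8/6/6 Type I genes (Mα/Mβ/Mγ) and 4/6 Type II genes
  (MIKC*/MIKC^C), 30 in all; three species, the first serving as the labeled
  reference set;
* a 5 × 400-kb assembly at GC 0.4 carrying the focal species' 30 genes plus
  30 length-matched decoy ORFs, 30% of planted genes withheld from the CDS
  track to exercise the genome-track rescue.

Duplication histories are caterpillars (each event copies the newest gene),
and every child is planted downstream of its parent with the rank gap its
class prescribes — tandem adjacent, proximal 2–10, distal on another contig.
Later insertions always land after the lineage's newest gene, so earlier
gaps are never disturbed and the one final-genealogy cherry per lineage
realizes exactly its planned class; the manifest records those classes, and
duplication statistics must reproduce them verbatim.  Genes are planted as
`TAA ATG … stop` so an in-frame stop immediately precedes the start codon
and the naive caller recovers the exact planted interval.  Everything is
byte-reproducible under a fixed seed.

What passing tests on this generator do **not** show: performance on real
genomes with introns (multi-exon genes need the external-predictor path),
repeat-derived false positives, sequencing error, or realistic amino-acid
substitution processes.

## Determinism and numerics

All randomness flows through `numpy.random.default_rng` seeds; reruns of any
subcommand with the same config and seed are byte-identical (timestamps exist
only in logs).  Branch lengths within −1e-9 of zero are clamped to zero
(midpoint arithmetic can produce −1e-18-scale values); anything more negative
is an error.  Profile serialization is a versioned plain-text table at
6-decimal fixed point, with rows renormalized on read.

## Problem sizes

The bundled study scales were chosen so the full suite and the acceptance
script each complete in a couple of minutes on a single CPU while still
exercising every code path at realistic signal-to-noise: a 2-Mb genome for
end-to-end recovery, 200-replicate oracle sweeps for NJ and duplication
counts, the exhaustive K ≤ 4 × length ≤ 6 enumeration for the DP core, and
reduced-scale (2 × 100 kb) fixtures for the per-module tests.  The
Monte-Carlo false-positive check in the unit suite uses 10 × 50-kb random
contigs; the wider-margin observation above (no random hit ≥ 20 bits in 30 ×
100-kb replicates) was measured with the same generator.
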