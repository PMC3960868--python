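"""Profile hidden Markov model of a protein domain family.

The model is the classic match/insert/delete architecture built from a seed
multiple alignment: columns whose gap fraction is below a threshold become
match states; the remaining columns are insert columns.  Scoring is
*single-domain local* log-odds alignment (Smith-Waterman-like): an alignment
enters at any match state (uniform 1/K entry probability), leaves from any
match state (free exit), and residues outside the aligned span are emitted at
background frequency, contributing 0 bits.  Insert states emit at background,
so inserts cost only their transitions.  All scores are in bits (log2).

This deliberately simple single-hit architecture fits domains that occur once
per protein, such as the 56-60 aa MADS DNA-binding domain; it trades HMMER's
multi-hit Plan7 machinery for a model that can be verified exhaustively
against path enumeration on small instances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from famscan.core_seq import SeqRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP = "-"
NEG_INF = float("-inf")


class ProfileError(ValueError):
    """Raised for malformed profiles or unscorable sequences."""


@dataclass
class ProfileHMM:
    """Position-specific emission/transition model of a domain family.

    Attributes
    ----------
    match_emissions : (K, 20) array
        Per-match-state residue probabilities (rows sum to 1).
    insert_emissions : (20,) array
        Shared insert-state emission distribution (the background).
    background : (20,) array
        Null-model residue frequencies.
    transitions : dict[str, np.ndarray]
        Arrays of length K-1 for the interior transitions, indexed by the
        source position m (0-based): ``mm``/``mi``/``md`` leave match state m,
        ``im``/``ii`` leave insert state m, ``dm``/``dd`` leave delete state
        m+1 (delete states D_1..D_{K-1} in 1-based terms; entry is always at a
        match state so D_0 does not exist).
    """

    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    background: np.ndarray
    transitions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        K = self.match_emissions.shape[0]
        if K < 1 or self.match_emissions.shape[1] != 20:
            raise ProfileError("match_emissions must be (K, 20) with K >= 1")
        self._validate()
        # Precompute log-odds emission table with an extra column for X
        # (scored at background, i.e. 0 bits).
        lo = np.log2(self.match_emissions / self.background[None, :])
        self._em_lo = np.hstack([lo, np.zeros((K, 1))])
        t = self.transitions
        if K > 1:
            self._log_t = {k: np.log2(t[k]) for k in t}
        else:
            self._log_t = {k: np.empty(0) for k in
                           ("mm", "mi", "md", "im", "ii", "dm", "dd")}
        self._entry = -np.log2(K)

    @property
    def K(self) -> int:
        return self.match_emissions.shape[0]

    def _validate(self, tol: float = 1e-9) -> None:
        if np.any(self.match_emissions <= 0) or np.any(self.background <= 0):
            raise ProfileError("probabilities must be > 0 after pseudocounting")
        if np.max(np.abs(self.match_emissions.sum(axis=1) - 1.0)) > tol:
            raise ProfileError("match emission rows must sum to 1")
        for vec in (self.insert_emissions, self.background):
            if abs(vec.sum() - 1.0) > tol:
                raise ProfileError("emission/background vectors must sum to 1")
        t = self.transitions
        K = self.match_emissions.shape[0]
        if K > 1:
            for trio, names in ((("mm", "mi", "md"), "match"),
                                (("im", "ii"), "insert"),
                                (("dm", "dd"), "delete")):
                total = sum(np.asarray(t[k], dtype=float) for k in trio)
                if np.max(np.abs(total - 1.0)) > tol:
                    raise ProfileError(f"{names}-state transitions must sum to 1")
                if any(np.any(np.asarray(t[k]) <= 0) for k in trio):
                    raise ProfileError("transition probabilities must be > 0")

    def encode(self, protein: str) -> np.ndarray:
        """Map a protein string to emission-table column indices (X -> 20)."""
        if not protein:
            raise ProfileError("protein must be non-empty")
        idx = np.empty(len(protein), dtype=np.int64)
        for i, a in enumerate(protein):
            if a == "X":
                idx[i] = 20
            else:
                j = AA_INDEX.get(a)
                if j is None:
                    raise ProfileError(f"residue {a!r} outside the amino-acid alphabet")
                idx[i] = j
        return idx


@dataclass
class DomainHit:
    """A scored local match of the profile to one target sequence."""

    target_id: str
    target_start: int
    target_end: int
    bit_score: float
    matched_states: tuple[int, int]  # first and last match state used, 0-based
    path: str | None = None  # e.g. "MMMIDMM" over the aligned span

    def __post_init__(self) -> None:
        if not self.target_start < self.target_end:
            raise ProfileError("hit span must be non-empty")
        if not np.isfinite(self.bit_score):
            raise ProfileError("bit score must be finite")


# ---------------------------------------------------------------------------
# Profile construction


def build_profile(seed_msa: Sequence[SeqRecord], gap_threshold: float = 0.5,
                  pseudocount_weight: float = 1.0) -> ProfileHMM:
    """Build a profile HMM from an aligned set of domain exemplars.

    Columns whose gap fraction is below ``gap_threshold`` become match states.
    Emissions use background-weighted Laplace pseudocounts:
    ``(count_a + w * q_a) / (depth + w)`` where ``q`` is the seed-wide residue
    frequency smoothed with a uniform pseudocount, ``depth`` the number of
    residues observed in the column and ``w`` the pseudocount weight.
    Transitions are estimated from each row's implied match/insert/delete path
    with a uniform pseudocount of ``w / n_alternatives`` per outgoing edge.
    """
    if not seed_msa:
        raise ProfileError("empty seed alignment")
    rows = [r.residues for r in seed_msa]
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ProfileError("seed alignment rows must have equal length")
    nrow = len(rows)
    w = float(pseudocount_weight)

    # Background from all seed residues, uniform-smoothed.
    counts = np.zeros(20)
    for row in rows:
        for a in row:
            if a in AA_INDEX:
                counts[AA_INDEX[a]] += 1
    background = (counts + 1.0) / (counts.sum() + 20.0)

    gap_frac = np.array(
        [sum(1 for row in rows if row[c] == GAP) / nrow for c in range(ncol)]
    )
    match_cols = [c for c in range(ncol) if gap_frac[c] < gap_threshold]
    K = len(match_cols)
    if K == 0:
        raise ProfileError("no match states: all columns exceed the gap threshold")

    match_emissions = np.empty((K, 20))
    for m, c in enumerate(match_cols):
        col_counts = np.zeros(20)
        for row in rows:
            a = row[c]
            if a in AA_INDEX:
                col_counts[AA_INDEX[a]] += 1
        depth = col_counts.sum()
        match_emissions[m] = (col_counts + w * background) / (depth + w)

    # Transition counts between consecutive match positions.  Each row yields
    # a path over the K match positions: M or D at each, with I events between.
    cnt = {k: np.zeros(max(K - 1, 0)) for k in ("mm", "mi", "md", "im", "ii", "dm", "dd")}
    match_set = set(match_cols)
    for row in rows:
        # state at each match position, and insert counts between them
        states = []
        inserts_after = np.zeros(K, dtype=int)
        m = -1
        for c in range(ncol):
            if c in match_set:
                m += 1
                states.append("D" if row[c] == GAP else "M")
            elif row[c] != GAP and 0 <= m < K:
                # residue in an insert column between match positions m, m+1
                inserts_after[m] += 1
        for m in range(K - 1):
            src, dst, n_ins = states[m], states[m + 1], inserts_after[m]
            if src == "M":
                if n_ins > 0:
                    cnt["mi"][m] += 1
                    cnt["ii"][m] += n_ins - 1
                    cnt["im"][m] += 1 if dst == "M" else 0
                    # insert followed by delete is not representable in this
                    # architecture; count it as I->M into the next match and a
                    # delete there is handled by the D path of that row.
                elif dst == "M":
                    cnt["mm"][m] += 1
                else:
                    cnt["md"][m] += 1
            else:  # src == "D"
                if dst == "M" or n_ins > 0:
                    cnt["dm"][m] += 1
                else:
                    cnt["dd"][m] += 1

    transitions: dict[str, np.ndarray] = {}
    if K > 1:
        m_tot = cnt["mm"] + cnt["mi"] + cnt["md"]
        i_tot = cnt["im"] + cnt["ii"]
        d_tot = cnt["dm"] + cnt["dd"]
        for k, tot, n_alt in (("mm", m_tot, 3), ("mi", m_tot, 3), ("md", m_tot, 3),
                              ("im", i_tot, 2), ("ii", i_tot, 2),
                              ("dm", d_tot, 2), ("dd", d_tot, 2)):
            transitions[k] = (cnt[k] + w / n_alt) / (tot + w)
    else:
        transitions = {k: np.empty(0) for k in cnt}

    return ProfileHMM(
        match_emissions=match_emissions,
        insert_emissions=background.copy(),
        background=background,
        transitions=transitions,
    )


# ---------------------------------------------------------------------------
# Scoring


def _viterbi_fast(hmm: ProfileHMM, idx: np.ndarray) -> float:
    """Best local-alignment bit score (no traceback), vectorized over states."""
    K = hmm.K
    em = hmm._em_lo
    entry = hmm._entry
    L = len(idx)
    if K == 1:
        return float(em[0, idx].max() + entry)
    t = hmm._log_t
    tmm, tmi, tmd = t["mm"], t["mi"], t["md"]
    tim, tii = t["im"], t["ii"]
    tdm, tdd = t["dm"], t["dd"]
    # Delete chains are folded into one vectorized pass per residue:
    # VD[j] holds the best score ending at delete state D_{j+1} (j = 0..K-2);
    # VD[j] = max_{k<=j} VM[k] + tmd[k] + sum_{l=k+1..j} tdd[l], computed as a
    # running maximum after subtracting the cumulative tdd sums cdd[j].
    cdd = np.concatenate([[0.0], np.cumsum(tdd[1:])]) if K > 2 else np.zeros(max(K - 1, 0))

    VM = em[:, idx[0]] + entry
    VI = np.full(K - 1, NEG_INF)
    A = VM[:-1] + tmd - cdd
    VD = np.maximum.accumulate(A) + cdd
    best = float(VM.max())
    for i in range(1, L):
        e = em[:, idx[i]]
        newVM = np.full(K, entry)
        np.maximum(newVM[1:], VM[:-1] + tmm, out=newVM[1:])
        np.maximum(newVM[1:], VI + tim, out=newVM[1:])
        if K > 2:
            # M_{m'} receives from D_{m'-1} (= VD index m'-2) via tdm[m'-1]
            np.maximum(newVM[2:], VD[:-1] + tdm[1:], out=newVM[2:])
        newVM += e
        newVI = np.maximum(VM[:-1] + tmi, VI + tii)
        VM, VI = newVM, newVI
        A = VM[:-1] + tmd - cdd
        VD = np.maximum.accumulate(A) + cdd
        m = float(VM.max())
        if m > best:
            best = m
    return best


def _forward_fast(hmm: ProfileHMM, idx: np.ndarray) -> float:
    """log2-sum of odds over all local alignment paths."""
    K = hmm.K
    em = hmm._em_lo
    entry = hmm._entry
    L = len(idx)
    if K == 1:
        return float(np.logaddexp2.reduce(em[0, idx] + entry))
    t = hmm._log_t
    tmm, tmi, tmd = t["mm"], t["mi"], t["md"]
    tim, tii = t["im"], t["ii"]
    tdm, tdd = t["dm"], t["dd"]
    cdd = np.concatenate([[0.0], np.cumsum(tdd[1:])]) if K > 2 else np.zeros(max(K - 1, 0))

    VM = em[:, idx[0]] + entry
    VI = np.full(K - 1, NEG_INF)
    A = VM[:-1] + tmd - cdd
    VD = np.logaddexp2.accumulate(A) + cdd
    total = np.logaddexp2.reduce(VM)
    for i in range(1, L):
        e = em[:, idx[i]]
        newVM = np.full(K, entry)
        newVM[1:] = np.logaddexp2(newVM[1:], VM[:-1] + tmm)
        newVM[1:] = np.logaddexp2(newVM[1:], VI + tim)
        if K > 2:
            newVM[2:] = np.logaddexp2(newVM[2:], VD[:-1] + tdm[1:])
        newVM += e
        newVI = np.logaddexp2(VM[:-1] + tmi, VI + tii)
        VM, VI = newVM, newVI
        A = VM[:-1] + tmd - cdd
        VD = np.logaddexp2.accumulate(A) + cdd
        total = np.logaddexp2.reduce(np.append(VM, total))
    return float(total)


def _viterbi_traceback(hmm: ProfileHMM, idx: np.ndarray):
    """Full Viterbi with backpointers; returns (score, i0, i1, m0, m1, path).

    ``[i0, i1)`` is the aligned residue span, ``m0``/``m1`` the first/last
    match state (0-based), ``path`` a string over {M, I, D}.  Ties prefer
    Match over Delete over Insert, and among equal-scoring cells the earliest
    end position and lowest end state.
    """
    K = hmm.K
    em = hmm._em_lo
    entry = hmm._entry
    L = len(idx)
    t = hmm._log_t
    VM = np.full((L, K), NEG_INF)
    VI = np.full((L, max(K - 1, 1)), NEG_INF)
    VD = np.full((L, max(K - 1, 1)), NEG_INF)
    # backpointers: 0=entry, 1=from M, 2=from D, 3=from I
    BM = np.zeros((L, K), dtype=np.int8)
    BI = np.zeros((L, max(K - 1, 1)), dtype=np.int8)
    BD = np.zeros((L, max(K - 1, 1)), dtype=np.int8)
    for i in range(L):
        for m in range(K):
            best, arg = entry, 0
            if i > 0 and m > 0:
                cands = [
                    (VM[i - 1, m - 1] + t["mm"][m - 1], 1),
                    (VI[i - 1, m - 1] + t["im"][m - 1], 3),
                ]
                if m > 1:
                    # from delete state D_{m-1} (VD index m-2)
                    cands.insert(1, (VD[i - 1, m - 2] + t["dm"][m - 1], 2))
                for v, a in cands:
                    if v > best:
                        best, arg = v, a
            VM[i, m] = em[m, idx[i]] + best
            BM[i, m] = arg
        for m in range(K - 1):
            # delete state D_{m+1}: from M_m (same residue index) or D_m
            best, arg = VM[i, m] + t["md"][m], 1
            if m > 0 and VD[i, m - 1] + t["dd"][m] > best:
                best, arg = VD[i, m - 1] + t["dd"][m], 2
            VD[i, m] = best
            BD[i, m] = arg
            if i > 0:
                # insert state I_m emits residue i at background (0 bits)
                bi, ai = VM[i - 1, m] + t["mi"][m], 1
                if VI[i - 1, m] + t["ii"][m] > bi:
                    bi, ai = VI[i - 1, m] + t["ii"][m], 3
                VI[i, m] = bi
                BI[i, m] = ai
    # best end cell
    end_i, end_m = 0, 0
    best = NEG_INF
    for i in range(L):
        for m in range(K):
            if VM[i, m] > best:
                best, end_i, end_m = VM[i, m], i, m
    # traceback
    path = []
    state, i, m = "M", end_i, end_m
    while True:
        path.append(state)
        if state == "M":
            b = BM[i, m]
            if b == 0:
                break
            if b == 1:
                state, i, m = "M", i - 1, m - 1
            elif b == 2:
                state, i, m = "D", i - 1, m - 2  # D_{m-1} has index m-2 in VD
            else:
                state, i, m = "I", i - 1, m - 1  # I_{m-1}? see below
        elif state == "D":
            # current is D_{m+1} at VD index m
            if BD[i, m] == 1:
                state = "M"  # M_m
            else:
                state, m = "D", m - 1
        else:  # state == "I", VI index m = insert state I_m
            if BI[i, m] == 1:
                state, i = "M", i - 1
            else:
                state, i = "I", i - 1
    path.reverse()
    start_i = end_i - sum(1 for s in path if s != "D") + 1
    start_m = end_m - sum(1 for s in path if s != "I") + 1
    return float(best), start_i, end_i + 1, start_m, end_m, "".join(path)


def viterbi_score(hmm: ProfileHMM, protein: str,
                  with_path: bool = True) -> tuple[float, str | None]:
    """Best single-domain local alignment score in bits, with its state path."""
    idx = hmm.encode(protein)
    if with_path:
        score, _i0, _i1, _m0, _m1, path = _viterbi_traceback(hmm, idx)
        return score, path
    return _viterbi_fast(hmm, idx), None


def forward_score(hmm: ProfileHMM, protein: str) -> float:
    """Total log-odds (bits) summed over all local alignments of one domain."""
    return _forward_fast(hmm, hmm.encode(protein))


def best_hit(hmm: ProfileHMM, record: SeqRecord) -> DomainHit:
    """Score one protein and return its best-span hit with path."""
    idx = hmm.encode(record.residues)
    score, i0, i1, m0, m1, path = _viterbi_traceback(hmm, idx)
    return DomainHit(
        target_id=record.id, target_start=i0, target_end=i1,
        bit_score=score, matched_states=(m0, m1), path=path,
    )


def scan_proteins(hmm: ProfileHMM, proteins: Sequence[SeqRecord],
                  threshold_bits: float) -> list[DomainHit]:
    """Scan proteins, keeping at most the best hit per sequence above threshold.

    Returns hits sorted by descending bit score (ties by target id).  The fast
    score-only pass filters; tracebacks are computed only for retained hits.
    """
    if not np.isfinite(threshold_bits):
        if threshold_bits > 0:
            return []
    hits: list[DomainHit] = []
    for rec in proteins:
        idx = hmm.encode(rec.residues)
        score = _viterbi_fast(hmm, idx)
        if score >= threshold_bits:
            hits.append(best_hit(hmm, rec))
    hits.sort(key=lambda h: (-h.bit_score, h.target_id))
    return hits


# ---------------------------------------------------------------------------
# Serialization: plain-text profile format, 6-decimal fixed point


_FMT_VERSION = "famscan-profile v1"


def write_profile(hmm: ProfileHMM, path: str | Path) -> None:
    """Serialize a profile to the documented plain-text table format."""
    with open(path, "w") as fh:
        fh.write(f"# {_FMT_VERSION}\n")
        fh.write(f"K\t{hmm.K}\n")
        fh.write("alphabet\t" + AMINO_ACIDS + "\n")
        fh.write("background\t" + "\t".join(f"{p:.6f}" for p in hmm.background) + "\n")
        fh.write("insert\t" + "\t".join(f"{p:.6f}" for p in hmm.insert_emissions) + "\n")
        fh.write("# match emissions, one row per state\n")
        for row in hmm.match_emissions:
            fh.write("match\t" + "\t".join(f"{p:.6f}" for p in row) + "\n")
        fh.write("# transitions mm mi md im ii dm dd, one row per inter-state gap\n")
        t = hmm.transitions
        for m in range(hmm.K - 1):
            vals = [t[k][m] for k in ("mm", "mi", "md", "im", "ii", "dm", "dd")]
            fh.write("trans\t" + "\t".join(f"{p:.6f}" for p in vals) + "\n")


def read_profile(path: str | Path) -> ProfileHMM:
    """Read a profile written by :func:`write_profile` (renormalizing rows)."""
    lines = [ln for ln in Path(path).read_text().splitlines()
             if ln and not ln.startswith("#")]
    fields = {"match": [], "trans": []}
    meta: dict[str, list[str]] = {}
    for ln in lines:
        key, *vals = ln.split("\t")
        if key in fields:
            fields[key].append([float(v) for v in vals])
        else:
            meta[key] = vals
    K = int(meta["K"][0])
    match = np.array(fields["match"])
    if match.shape != (K, 20):
        raise ProfileError(f"profile file has {match.shape} match rows, expected ({K}, 20)")
    match /= match.sum(axis=1, keepdims=True)
    background = np.array([float(v) for v in meta["background"]])
    background /= background.sum()
    insert = np.array([float(v) for v in meta["insert"]])
    insert /= insert.sum()
    trans_rows = np.array(fields["trans"]) if fields["trans"] else np.empty((0, 7))
    keys = ("mm", "mi", "md", "im", "ii", "dm", "dd")
    transitions = {k: trans_rows[:, i].copy() for i, k in enumerate(keys)}
    if K > 1:
        for trio in (("mm", "mi", "md"), ("im", "ii"), ("dm", "dd")):
            tot = sum(transitions[k] for k in trio)
            for k in trio:
                transitions[k] = transitions[k] / tot
    return ProfileHMM(match_emissions=match, insert_emissions=insert,
                      background=background, transitions=transitions)


def write_hits_tsv(hits: Iterable[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("target_id\ttarget_start\ttarget_end\tbit_score\n")
        for h in hits:
            fh.write(f"{h.target_id}\t{h.target_start}\t{h.target_end}\t{h.bit_score:.4f}\n")
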