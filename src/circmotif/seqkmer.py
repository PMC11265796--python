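"""Circular k-mer enumeration, consensus assembly and degenerate motif scanning.

Circular RNAs are covalently closed, so k-mer windows wrap around the
backsplice junction: a circular sequence of length L has exactly L windows of
length k, while a linear sequence has L - k + 1.  All coordinates are 0-based
half-open (BED convention).  RNA input is accepted and normalised U->T once on
ingestion, so DNA and RNA motifs compare directly.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CircularSequence",
    "KmerTable",
    "ConsensusMotif",
    "ScanParams",
    "MotifMatch",
    "BipartitePattern",
    "normalize_sequence",
    "enumerate_kmers",
    "assemble_consensus",
    "scan_motif",
    "scan_bipartite",
    "hamming_mismatches",
    "reverse_complement",
]

# IUPAC nucleotide codes -> set of matching bases (DNA alphabet)
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
_SET_TO_IUPAC = {v: k for k, v in IUPAC.items()}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# uint8 encoding for vectorised scanning
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def normalize_sequence(seq: str, allow_iupac: bool = False) -> str:
    """Uppercase, map U->T, and validate the alphabet.

    Plain sequences must be ACGT after mapping; with ``allow_iupac`` the full
    degenerate alphabet is accepted (used for consensus strings).
    """
    s = seq.upper().replace("U", "T")
    allowed = IUPAC.keys() if allow_iupac else "ACGT"
    bad = set(s) - set(allowed)
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    return normalize_sequence(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CircularSequence:
    """A nucleotide sequence with a circularity flag."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class KmerTable:
    """All k-mer windows of a (possibly circular) sequence.

    positions maps each k-mer to the sorted list of 0-based start positions on
    the original sequence; wrap-around windows keep their start in [0, L).
    """

    k: int
    positions: dict[str, list[int]]
    circular: bool
    sequence_length: int

    @property
    def n_unique(self) -> int:
        return len(self.positions)

    @property
    def n_windows(self) -> int:
        return sum(len(v) for v in self.positions.values())

    def multiplicity(self, kmer: str) -> int:
        return len(self.positions.get(kmer, ()))

    @property
    def max_multiplicity(self) -> int:
        return max((len(v) for v in self.positions.values()), default=0)

    def kmers(self) -> list[str]:
        return sorted(self.positions)


def enumerate_kmers(seq: CircularSequence | str, k: int, circular: bool | None = None) -> KmerTable:
    """Enumerate every k-mer window of *seq*.

    Circular mode yields exactly L windows (wrap-around across the backsplice
    junction included); linear mode yields L - k + 1.
    """
    if isinstance(seq, CircularSequence):
        s = seq.sequence
        circ = seq.circular if circular is None else circular
    else:
        s = normalize_sequence(seq)
        circ = True if circular is None else circular
    L = len(s)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > L:
        raise ValueError(f"k={k} exceeds sequence length {L}")
    text = s + s[: k - 1] if circ else s
    n_windows = L if circ else L - k + 1
    positions: dict[str, list[int]] = {}
    for i in range(n_windows):
        positions.setdefault(text[i : i + k], []).append(i)
    return KmerTable(k=k, positions=positions, circular=circ, sequence_length=L)


# ---------------------------------------------------------------------------
# Consensus assembly
# ---------------------------------------------------------------------------


@dataclass
class ConsensusMotif:
    """Degenerate IUPAC consensus assembled from aligned k-mers.

    members are (kmer, offset) placements relative to the consensus start
    (offset 0 = leftmost position of the consensus); unplaced lists the k-mers
    whose best alignment exceeded the mismatch budget.
    """

    consensus: str
    members: list[tuple[str, int]]
    unplaced: list[str] = field(default_factory=list)
    base_counts: list[Counter] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.consensus)


def _sets_to_consensus(sets: list[set[str]]) -> str:
    return "".join(_SET_TO_IUPAC[frozenset(s)] for s in sets)


def _best_offset(kmer: str, col_sets: list[set[str]], lo: int, hi: int, min_overlap: int):
    """Best placement of *kmer* against the current per-column base sets.

    Offsets range over [lo, hi]; a column mismatch is a base not in the
    column's observed set; columns outside the current consensus span are free.
    Ties: lowest mismatches, then smallest |offset|, then leftmost.
    """
    k = len(kmer)
    n = len(col_sets)
    best = None
    for off in range(lo, hi + 1):
        overlap = 0
        mism = 0
        for j, base in enumerate(kmer):
            col = off + j
            if 0 <= col < n:
                overlap += 1
                if base not in col_sets[col]:
                    mism += 1
        if overlap < min_overlap:
            continue
        key = (mism, abs(off), off)
        if best is None or key < best[0]:
            best = (key, off, mism)
    if best is None:
        return None
    return best[1], best[2]


def assemble_consensus(
    kmers: list[str],
    max_internal_mismatch: int = 1,
    min_overlap: int | None = None,
    trim_degenerate_edges: bool = True,
) -> ConsensusMotif:
    """Assemble a degenerate consensus from overlapping k-mers.

    The first k-mer in the list is the anchor (callers pass k-mers
    best-scoring first).  Remaining k-mers are placed greedily at the offset
    minimising mismatches against the columns observed so far, requiring at
    least ``min_overlap`` aligned columns (default k - 1: a one-base shift,
    the tightest overlap seen among genuinely shifted k-mers).  Placement is
    repeated in passes so that a k-mer whose anchor-distance exceeds one shift
    can still join once the consensus has grown toward it.  K-mers that never
    fit within the mismatch budget are reported as unplaced, not dropped.
    Columns where more than one base occurs among members become IUPAC
    degenerate codes.

    A terminal column where members outright disagree (more than one base, so
    the column would be called degenerate) carries flanking-context noise
    rather than motif structure — it arises when k-mers extending past the
    true motif boundary drag in their heterogeneous neighbouring base.  With
    ``trim_degenerate_edges`` such columns are trimmed iteratively from both
    ends; members then keep their placement and may overhang the trimmed
    consensus (overhanging bases are outside the consensus and count no
    mismatches).  Unambiguous terminal columns, even singly supported, are
    never trimmed.
    """
    if not kmers:
        raise ValueError("need at least one k-mer")
    kmers = [normalize_sequence(km) for km in kmers]
    k = len(kmers[0])
    if any(len(km) != k for km in kmers):
        raise ValueError("all k-mers must have equal length")
    if min_overlap is None:
        min_overlap = max(1, k - 1)

    # col_sets[i] = set of bases observed in column i; origin shifts as the
    # consensus grows left, tracked so member offsets stay consistent.
    col_sets: list[set[str]] = [set(b) for b in kmers[0]]
    counts: list[Counter] = [Counter(b) for b in kmers[0]]
    placements: dict[int, int] = {0: 0}  # input index -> offset in col space
    origin = 0  # offset of col_sets[0] relative to the anchor

    # Mismatch-tiered placement: exhaust perfect (0-mismatch) placements before
    # admitting any mismatch, so the consensus grows along perfect overlaps and
    # a k-mer two shifts from the seed is not mis-placed early at one mismatch.
    remaining = list(range(1, len(kmers)))
    for tier in range(0, max_internal_mismatch + 1):
        changed = True
        while changed and remaining:
            changed = False
            still = []
            for idx in remaining:
                km = kmers[idx]
                lo, hi = -(k - 1), len(col_sets) - 1  # any overlap >= 1 column
                found = _best_offset(km, col_sets, lo, hi, min_overlap)
                if found is None or found[1] > tier:
                    still.append(idx)
                    continue
                off, _ = found
                # grow columns to the left/right as needed
                if off < 0:
                    col_sets[:0] = [set() for _ in range(-off)]
                    counts[:0] = [Counter() for _ in range(-off)]
                    origin += off
                    for j in placements:
                        placements[j] -= off
                    off = 0
                while off + k > len(col_sets):
                    col_sets.append(set())
                    counts.append(Counter())
                for j, base in enumerate(km):
                    col_sets[off + j].add(base)
                    counts[off + j][base] += 1
                placements[idx] = off
                changed = True
            remaining = still

    shift = 0
    if trim_degenerate_edges:
        while len(col_sets) > 1 and len(col_sets[0]) > 1:
            col_sets.pop(0)
            counts.pop(0)
            shift += 1
        while len(col_sets) > 1 and len(col_sets[-1]) > 1:
            col_sets.pop()
            counts.pop()

    consensus = _sets_to_consensus(col_sets)
    members = [(kmers[i], placements[i] - shift) for i in sorted(placements)]
    unplaced = [kmers[i] for i in remaining]
    return ConsensusMotif(consensus=consensus, members=members, unplaced=unplaced, base_counts=counts)


# ---------------------------------------------------------------------------
# Mismatch-tolerant scanning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanParams:
    """Parameters for the degenerate-consensus scan."""

    max_mismatches: int = 2

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class MotifMatch:
    sequence_id: str
    start: int
    end: int
    mismatches: int


def hamming_mismatches(window: str, consensus: str) -> int:
    """Mismatch count of *window* against an IUPAC *consensus* (equal length).

    A base matches a degenerate letter iff it belongs to the letter's IUPAC
    set; such positions contribute zero mismatches.
    """
    if len(window) != len(consensus):
        raise ValueError("length mismatch")
    return sum(b not in IUPAC[c] for b, c in zip(window, consensus))


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _consensus_tables(consensus: str) -> np.ndarray:
    """(motif_len, 256) boolean lookup: does ASCII byte match position i."""
    W = len(consensus)
    tab = np.zeros((W, 256), dtype=bool)
    for i, letter in enumerate(consensus):
        for b in IUPAC[letter]:
            tab[i, ord(b)] = True
    return tab


def scan_motif(
    seq: str,
    consensus: ConsensusMotif | str,
    params: ScanParams = ScanParams(),
    sequence_id: str = "",
) -> list[MotifMatch]:
    """All windows of *seq* within the mismatch budget of the consensus.

    Scanning is single-strand; overlapping matches are all reported.
    """
    cons = consensus.consensus if isinstance(consensus, ConsensusMotif) else consensus
    cons = normalize_sequence(cons, allow_iupac=True)
    s = normalize_sequence(seq)
    W = len(cons)
    L = len(s)
    if L < W:
        return []
    enc = _encode(s)
    tab = _consensus_tables(cons)
    n_win = L - W + 1
    mism = np.zeros(n_win, dtype=np.int32)
    for i in range(W):
        mism += ~tab[i][enc[i : i + n_win]]
    hits = np.flatnonzero(mism <= params.max_mismatches)
    return [MotifMatch(sequence_id, int(p), int(p) + W, int(mism[p])) for p in hits]


# ---------------------------------------------------------------------------
# Bipartite element scanning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BipartitePattern:
    """Bipartite recognition element: 5' literal, variable spacer, degenerate 3' box.

    The default is the KH34 high-affinity element of the IGF2BP family:
    CTCAC, a 10-15 nt spacer, then (A/T)GG(A/T).
    """

    five_prime: str = "CTCAC"
    spacer_min: int = 10
    spacer_max: int = 15
    three_prime: str = "WGGW"

    def __post_init__(self) -> None:
        if self.spacer_min > self.spacer_max:
            raise ValueError("spacer_min must be <= spacer_max")
        object.__setattr__(self, "five_prime", normalize_sequence(self.five_prime, allow_iupac=True))
        object.__setattr__(self, "three_prime", normalize_sequence(self.three_prime, allow_iupac=True))


def _iupac_regex(s: str) -> str:
    return "".join(b if len(IUPAC[b]) == 1 else "[" + "".join(sorted(IUPAC[b])) + "]" for b in s)


def scan_bipartite(seq: str, pattern: BipartitePattern = BipartitePattern(), sequence_id: str = "") -> list[MotifMatch]:
    """Every placement of 5' box + spacer in range + 3' box, one per spacer length.

    Overlapping placements and multiple valid spacer lengths at the same start
    are all reported (mismatches field is 0: boxes are matched exactly up to
    degeneracy).
    """
    s = normalize_sequence(seq)
    five = _iupac_regex(pattern.five_prime)
    three = _iupac_regex(pattern.three_prime)
    out: list[MotifMatch] = []
    for spacer in range(pattern.spacer_min, pattern.spacer_max + 1):
        rx = re.compile(f"(?=({five}.{{{spacer}}}{three}))")
        width = len(pattern.five_prime) + spacer + len(pattern.three_prime)
        for m in rx.finditer(s):
            out.append(MotifMatch(sequence_id, m.start(), m.start() + width, 0))
    out.sort(key=lambda mm: (mm.start, mm.end))
    return out
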