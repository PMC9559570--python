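"""Quadripartite plastome structure: inverted-repeat detection, canonical
linearization, SSC-orientation haplotypes, and recombination-model rearrangements.

A typical plastome is a circular molecule organized as four elementary regions,
LSC-IR1-SSC-IR2: a large and a small single-copy region separated by two
near-identical inverted repeats (IR2 is the reverse complement of IR1).  All
coordinates here are 0-based half-open on the canonical linearization (LSC
starting at offset 0); human-facing reports convert to 1-based inclusive.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import reverse_complement

__all__ = [
    "CircularGenome",
    "QuadripartiteStructure",
    "HaplotypePair",
    "SVSpec",
    "HSP",
    "HspScoring",
    "NoInvertedRepeatError",
    "PalindromicOverlapError",
    "StructureValidationError",
    "find_inverted_repeat_pair",
    "canonicalize",
    "flip_ssc",
    "build_haplotype_pair",
    "apply_ir_duplication",
    "apply_ir_loss",
    "find_hsp",
]

_ALPHABET = frozenset("ACGTN")

Interval = tuple[int, int]


class StructureValidationError(ValueError):
    """Genome/structure inconsistency or invalid rearrangement parameters."""


class NoInvertedRepeatError(RuntimeError):
    """No inverted-repeat pair of the requested length exists in the genome."""


class PalindromicOverlapError(RuntimeError):
    """The only candidate repeat pair would overlap itself (palindrome)."""


@dataclass(frozen=True)
class CircularGenome:
    """An uppercase nucleotide sequence with circular topology."""

    id: str
    seq: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.seq:
            raise StructureValidationError("genome sequence must be non-empty")
        bad = set(self.seq) - _ALPHABET
        if bad:
            raise StructureValidationError(
                f"genome {self.id!r} contains invalid characters: {sorted(bad)!r} "
                "(expected uppercase A/C/G/T/N)"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def rotated(self, offset: int) -> "CircularGenome":
        """Rotate so that input position ``offset`` becomes position 0."""
        if not self.circular and offset % len(self) != 0:
            raise StructureValidationError("cannot rotate a linear sequence")
        off = offset % len(self)
        return replace(self, seq=self.seq[off:] + self.seq[:off])

    def reverse_complement(self) -> "CircularGenome":
        return replace(self, seq=reverse_complement(self.seq))

    def fetch(self, start: int, length: int) -> str:
        """Circular substring of ``length`` bases starting at ``start``."""
        n = len(self)
        start %= n
        if not self.circular and start + length > n:
            raise StructureValidationError("fetch beyond end of linear sequence")
        doubled = self.seq + self.seq
        if length > n:
            raise StructureValidationError("fetch longer than the genome")
        return doubled[start : start + length]


@dataclass(frozen=True)
class QuadripartiteStructure:
    """Partition of a plastome into LSC, IR1, SSC, IR2 on the canonical rotation.

    ``rotation`` is the offset in the *source* sequence at which the canonical
    origin (first base of LSC) sits; a canonicalized genome has rotation 0.
    """

    lsc: Interval
    ir1: Interval
    ssc: Interval
    ir2: Interval
    ir_len: int
    ir_mismatches: int
    rotation: int = 0

    def __post_init__(self) -> None:
        regions = [self.lsc, self.ir1, self.ssc, self.ir2]
        for (a, b), (c, d) in zip(regions, regions[1:]):
            if b != c:
                raise StructureValidationError("regions must be contiguous and ordered")
        if self.lsc[0] != 0:
            raise StructureValidationError("LSC must start at canonical offset 0")
        if self.ir1[1] - self.ir1[0] != self.ir_len or self.ir2[1] - self.ir2[0] != self.ir_len:
            raise StructureValidationError("IR intervals must both have length ir_len")
        if self.lsc_len < self.ssc_len:
            raise StructureValidationError("LSC must be at least as long as SSC")

    @property
    def lsc_len(self) -> int:
        return self.lsc[1] - self.lsc[0]

    @property
    def ssc_len(self) -> int:
        return self.ssc[1] - self.ssc[0]

    @property
    def total_len(self) -> int:
        return self.ir2[1]

    @property
    def region_lengths(self) -> dict[str, int]:
        return {
            "LSC": self.lsc_len,
            "IR1": self.ir_len,
            "SSC": self.ssc_len,
            "IR2": self.ir_len,
        }

    def validate_for(self, genome: CircularGenome) -> None:
        if self.total_len != len(genome):
            raise StructureValidationError(
                f"structure covers {self.total_len} bp but genome is {len(genome)} bp"
            )

    @classmethod
    def from_lengths(
        cls, lsc_len: int, ir_len: int, ssc_len: int,
        ir_mismatches: int = 0, rotation: int = 0,
    ) -> "QuadripartiteStructure":
        a, b, c = lsc_len, lsc_len + ir_len, lsc_len + ir_len + ssc_len
        return cls(
            lsc=(0, a), ir1=(a, b), ssc=(b, c), ir2=(c, c + ir_len),
            ir_len=ir_len, ir_mismatches=ir_mismatches, rotation=rotation,
        )


@dataclass(frozen=True)
class HaplotypePair:
    """The two SSC-orientation haplotypes of one plastome.

    ``seq_f`` carries the SSC forward (LSC-IR1-SSC-IR2, the "wild" type);
    ``seq_r`` carries it reverse-complemented in place (LSC-IR1-ssc-IR2).
    """

    seq_f: CircularGenome
    seq_r: CircularGenome
    structure: QuadripartiteStructure


@dataclass(frozen=True)
class SVSpec:
    """Geometry of the IR-duplication rearrangement (asymmetric recombination).

    The mutant deletes the last ``d1_len`` bases of IR1 and inserts, at that
    point, ``insert_prefix`` + the first ``i1_len`` bases of LSC + a full copy
    of IR1, producing the IR1d-prefix-i1-IR1 junction organization.
    """

    d1_len: int
    i1_len: int
    insert_prefix: str = ""

    def insert_len(self, ir_len: int) -> int:
        return len(self.insert_prefix) + self.i1_len + ir_len

    def length_delta(self, ir_len: int) -> int:
        return self.insert_len(ir_len) - self.d1_len


@dataclass(frozen=True)
class HspScoring:
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


@dataclass(frozen=True)
class HSP:
    """High-score segment pair: the best local alignment between two sequences."""

    interval_a: Interval
    interval_b: Interval
    score: float
    scoring: HspScoring = field(default_factory=HspScoring)

    @property
    def is_empty(self) -> bool:
        return self.interval_a[0] == self.interval_a[1]


# ---------------------------------------------------------------------------
# inverted-repeat detection


_COMP_TABLE = np.full(256, ord("."), dtype=np.uint8)
for _x, _y in zip(b"ACGT", b"TGCA"):
    _COMP_TABLE[_x] = _y
# N deliberately maps to '.', so N never matches anything (including N)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _candidate_antidiagonals(s2: str, k: int, max_occ: int = 64) -> set[int]:
    """Anti-diagonals supported by at least one exact inverted k-mer seed.

    An inverted-repeat pair (a, b, L) with S[a:a+L] == revcomp(S[b:b+L]) places
    all of its internal seeds on the single anti-diagonal C = a + b + L - 1.
    """
    index: dict[str, list[int]] = {}
    for i in range(len(s2) - k + 1):
        index.setdefault(s2[i : i + k], []).append(i)
    rc2 = reverse_complement(s2)
    L2 = len(s2)
    cands: set[int] = set()
    for p in range(L2 - k + 1):
        kmer = rc2[p : p + k]
        hits = index.get(kmer)
        if hits is None or len(hits) > max_occ:
            continue
        j = L2 - p - k  # start of the partner segment on s2
        for i in hits:
            if i < j:  # each pair once, left copy first
                cands.add(i + j + k - 1)
    return cands


def _best_window(
    m: np.ndarray, offset: int, rate: float, max_budget: int
) -> tuple[int, int, int] | None:
    """Longest window in match-vector ``m`` with mismatches <= ceil(rate*len).

    Returns (start, length, mismatches) in absolute coordinates (``offset`` is
    the index of m[0]); window endpoints are trimmed to matching positions.
    """
    if m.size == 0:
        return None
    c = np.concatenate([[0], np.cumsum(~m)])
    best: tuple[int, int, int] | None = None
    ends = np.arange(1, m.size + 1)
    for budget in range(max_budget + 1):
        starts = np.searchsorted(c, c[1:] - budget, side="left")
        lengths = ends - starts
        mism = c[ends] - c[starts]
        ok = mism <= np.ceil(rate * lengths) if rate > 0 else (mism == 0)
        if not ok.any():
            continue
        idx = np.flatnonzero(ok)
        order = np.lexsort((starts[idx], -lengths[idx]))
        for j in order[: 32]:
            e = int(ends[idx[j]])
            s = int(starts[idx[j]])
            while s < e and not m[s]:
                s += 1
            while e > s and not m[e - 1]:
                e -= 1
            if e <= s:
                continue
            mm = int(c[e] - c[s])
            cand = (s + offset, e - s, mm)
            if best is None or (cand[1], -cand[2], -cand[0]) > (best[1], -best[2], -best[0]):
                best = cand
            break
    return best


def _scan_antidiagonal(
    s2v: np.ndarray, comp2v: np.ndarray, C: int, n: int,
    rate: float, max_budget: int, constrained: bool,
) -> tuple[int, int, int] | None:
    """Best inverted-match window on anti-diagonal C of the doubled sequence.

    With ``constrained`` the window must map to a pair of segments that are
    disjoint on the circle with at least one base of single-copy gap on each
    side: window end e satisfies 2e <= C (no palindromic self-overlap, gap
    after the left copy) and window start a >= (C+2-n)/2 (gap after the
    right copy, wrapping).
    """
    L2 = 2 * n
    i_lo = max(0, C - L2 + 1)
    i_hi = min(L2, C + 1)
    if constrained:
        i_lo = max(i_lo, -(-(C + 2 - n) // 2))
        i_hi = min(i_hi, C // 2)
    if i_hi <= i_lo:
        return None
    partner = comp2v[C - i_hi + 1 : C - i_lo + 1][::-1]
    m = s2v[i_lo:i_hi] == partner
    return _best_window(m, i_lo, rate, max_budget)


def _hamming_rc(a: str, b: str) -> int:
    """Mismatches between ``a`` and reverse_complement(``b``) (N never matches)."""
    av = _encode(a)
    bv = _COMP_TABLE[_encode(b)][::-1]
    return int((av != bv).sum())


def find_inverted_repeat_pair(
    genome: CircularGenome,
    min_len: int = 1000,
    max_mismatch_rate: float = 0.0,
    k: int = 15,
) -> QuadripartiteStructure:
    """Detect the inverted-repeat pair and partition the plastome.

    Searches all rotations of the circular sequence for the highest-scoring
    pair of disjoint segments in which one equals the reverse complement of
    the other up to ``max_mismatch_rate`` (ties: longest, then fewest
    mismatches, then smallest start offset).  The two gaps between the pair
    become LSC (the longer) and SSC; the result is reported on the canonical
    rotation with LSC at offset 0, plus the ``rotation`` offset locating that
    origin in the input.

    Raises :class:`NoInvertedRepeatError` if no pair of length >= ``min_len``
    exists, and :class:`PalindromicOverlapError` if the only candidate would
    overlap itself.
    """
    n = len(genome)
    if n < 4 * min_len:
        raise StructureValidationError(
            f"genome of {n} bp is shorter than 4*min_len ({4 * min_len} bp)"
        )
    if not genome.circular:
        raise StructureValidationError("inverted-repeat search requires a circular genome")
    k_eff = max(4, min(k, min_len))
    s2 = genome.seq + genome.seq
    s2v = _encode(s2)
    comp2v = _COMP_TABLE[s2v]
    max_budget = int(max_mismatch_rate * (n // 2))
    cands = _candidate_antidiagonals(s2, k_eff)

    candidates: list[tuple[int, int, int, int, int]] = []  # (L, mism, min_start, a, C)
    best_any = 0  # longest window ignoring the disjointness constraint
    seen: set[tuple[int, int, int]] = set()
    for C in sorted(cands):
        hit = _scan_antidiagonal(s2v, comp2v, C, n, max_mismatch_rate, max_budget, True)
        if hit is not None and hit[1] >= min_len:
            a, L, mm = hit
            b = C + 1 - L - a
            key = (min(a % n, b % n), max(a % n, b % n), L)
            if key not in seen:
                seen.add(key)
                candidates.append((L, mm, key[0], a, C))
        loose = _scan_antidiagonal(s2v, comp2v, C, n, max_mismatch_rate, max_budget, False)
        if loose is not None:
            best_any = max(best_any, loose[1])

    if not candidates:
        if best_any >= min_len:
            raise PalindromicOverlapError(
                f"longest inverted match ({best_any} bp) overlaps itself; "
                "no disjoint repeat pair exists"
            )
        raise NoInvertedRepeatError(
            f"no inverted-repeat pair of length >= {min_len} bp found"
        )

    # Rank by (longest, fewest mismatches, smallest start); degenerate pairs
    # whose copies are adjacent on the circle (no single-copy gap) fall
    # through to the next-best pair.
    for L, mm, _, a, C in sorted(candidates, key=lambda t: (-t[0], t[1], t[2])):
        b = C + 1 - L - a
        a_mod, b_mod = a % n, b % n
        gap1 = (b_mod - (a_mod + L)) % n
        gap2 = (a_mod - (b_mod + L)) % n
        if gap1 == 0 or gap2 == 0:
            continue
        if gap1 == gap2:
            raise StructureValidationError(
                "single-copy regions have equal length; LSC/SSC assignment is unresolvable"
            )
        if gap1 > gap2:
            lsc_len, ssc_len = gap1, gap2
            origin = (a_mod + L) % n  # LSC follows arc1; IR1 is arc2
        else:
            lsc_len, ssc_len = gap2, gap1
            origin = (b_mod + L) % n  # LSC follows arc2; IR1 is arc1
        structure = QuadripartiteStructure.from_lengths(
            lsc_len, L, ssc_len, ir_mismatches=mm, rotation=origin
        )
        structure.validate_for(genome)
        return structure
    raise NoInvertedRepeatError(
        "all candidate repeat pairs leave no single-copy regions"
    )


def canonicalize(
    genome: CircularGenome, structure: QuadripartiteStructure
) -> tuple[CircularGenome, QuadripartiteStructure]:
    """Rotate so that LSC begins at offset 0.  Idempotent."""
    structure.validate_for(genome)
    if structure.rotation % len(genome) == 0:
        return genome, replace(structure, rotation=0)
    return genome.rotated(structure.rotation), replace(structure, rotation=0)


def _require_canonical(genome: CircularGenome, structure: QuadripartiteStructure) -> None:
    structure.validate_for(genome)
    if structure.rotation % len(genome) != 0:
        raise StructureValidationError(
            "operation requires a canonical structure (rotation 0); "
            "call canonicalize() first"
        )


def flip_ssc(genome: CircularGenome, structure: QuadripartiteStructure) -> CircularGenome:
    """Replace the SSC interval by its reverse complement (SSC switching).

    This is the large SSC inversion produced by recombination between the two
    IRs; applying it twice restores the input.
    """
    _require_canonical(genome, structure)
    s, e = structure.ssc
    seq = genome.seq
    return replace(genome, seq=seq[:s] + reverse_complement(seq[s:e]) + seq[e:])


def build_haplotype_pair(
    genome: CircularGenome, structure: QuadripartiteStructure
) -> HaplotypePair:
    """Construct the SSC-F / SSC-R haplotype pair from a canonical genome."""
    _require_canonical(genome, structure)
    return HaplotypePair(
        seq_f=genome, seq_r=flip_ssc(genome, structure), structure=structure
    )


def apply_ir_duplication(
    genome: CircularGenome, structure: QuadripartiteStructure, sv: SVSpec
) -> CircularGenome:
    """Apply the IR-duplication rearrangement (the "mutant-3" product).

    Deletes the last ``d1_len`` bases of IR1 (leaving IR1d) and inserts
    ``insert_prefix`` + the first ``i1_len`` bases of LSC + a full IR1 copy at
    that point.  The resulting organization around the breakpoint is
    IR1d-prefix-i1-IR1 and the net length change is
    ``insert_len - d1_len``.
    """
    _require_canonical(genome, structure)
    if not 0 <= sv.d1_len < structure.ir_len:
        raise StructureValidationError("d1_len must be in [0, ir_len)")
    if not 0 <= sv.i1_len < structure.lsc_len:
        raise StructureValidationError("i1_len must be in [0, lsc_len)")
    if set(sv.insert_prefix) - _ALPHABET:
        raise StructureValidationError("insert_prefix must be over A/C/G/T/N")
    seq = genome.seq
    lsc = seq[slice(*structure.lsc)]
    ir1 = seq[slice(*structure.ir1)]
    ir1d = ir1[: structure.ir_len - sv.d1_len]
    insert = sv.insert_prefix + lsc[: sv.i1_len] + ir1
    mutant = seq[: structure.ir1[0]] + ir1d + insert + seq[structure.ir1[1] :]
    return replace(genome, id=genome.id + "_irdup", seq=mutant)


def apply_ir_loss(
    genome: CircularGenome, structure: QuadripartiteStructure
) -> CircularGenome:
    """Remove one full IR copy (IR2), yielding the LSC-IR-SSC organization."""
    _require_canonical(genome, structure)
    seq = genome.seq
    return replace(
        genome,
        id=genome.id + "_irloss",
        seq=seq[: structure.ir2[0]] + seq[structure.ir2[1] :],
    )


# ---------------------------------------------------------------------------
# local alignment (high-score segment pair)


def _make_aligner(scoring: HspScoring) -> PairwiseAligner:
    letters = "ACGTN"
    mat = substitution_matrices.Array(letters, dims=2)
    for x in letters:
        for y in letters:
            if x == y and x != "N":
                mat[x, y] = scoring.match
            else:
                mat[x, y] = scoring.mismatch
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def local_alignment_score(a: str, b: str, scoring: HspScoring | None = None) -> float:
    """Best local-alignment score under the HSP scheme (0 if nothing aligns)."""
    scoring = scoring or HspScoring()
    if not a or not b:
        return 0.0
    score = _make_aligner(scoring).score(a, b)
    return max(0.0, float(score))


def find_hsp(a: str, b: str, scoring: HspScoring | None = None) -> HSP:
    """Return the maximal local-alignment segment pair between two sequences.

    Default scoring: match +2, mismatch -3, gap -5 for the first gap column
    and -2 for each additional column (N matches nothing).  Ties among
    equal-scoring optima are broken by the smallest start in ``a``, then in
    ``b``.  If no segment pair scores above zero an empty HSP is returned.
    """
    scoring = scoring or HspScoring()
    if not a or not b:
        raise ValueError("find_hsp requires two non-empty sequences")
    aligner = _make_aligner(scoring)
    score = float(aligner.score(a, b))
    if score <= 0:
        return HSP((0, 0), (0, 0), 0.0, scoring)
    alignments = aligner.align(a, b)
    best: tuple[tuple[int, int], tuple[int, int]] | None = None
    for aln in itertools.islice(alignments, 256):
        blocks_a, blocks_b = aln.aligned
        ia = (int(blocks_a[0][0]), int(blocks_a[-1][1]))
        ib = (int(blocks_b[0][0]), int(blocks_b[-1][1]))
        if best is None or (ia[0], ib[0]) < (best[0][0], best[1][0]):
            best = (ia, ib)
    assert best is not None
    return HSP(best[0], best[1], score, scoring)
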