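"""Short tandem repeat (STR) detection and copy-number variation calling.

STRs — homopolymers (unit length 1) up through hexanucleotide repeats — are
the dominant source of small-scale plastome variation, and their copy number
can vary between molecules of a single individual (heteroplasmy).  Loci are
written in the compact ``pos[unit]min-max`` notation, e.g. ``11291[T]7-8``:
1-based genomic position, repeat unit in brackets, observed copy-number
range.  Copy numbers are counted per read between exact flanking anchors
rather than from alignment gaps, which is robust to how aligners place gaps
inside homopolymers.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import edlib
from Bio.Seq import reverse_complement

from .classify import ReadAlignment

__all__ = [
    "STRLocus",
    "find_str_loci",
    "str_copy_numbers",
    "format_str_notation",
    "parse_str_notation",
    "STRNotationError",
    "DEFAULT_MIN_COPIES",
]

#: minimum reference copy number to report a locus, by unit length
DEFAULT_MIN_COPIES: dict[int, int] = {1: 6, 2: 3, 3: 3, 4: 3, 5: 3, 6: 3}


class STRNotationError(ValueError):
    """Malformed STR descriptor text."""


def _least_rotation(s: str) -> str:
    return min(s[i:] + s[:i] for i in range(len(s)))


def _minimal_period(s: str) -> int:
    for p in range(1, len(s)):
        if len(s) % p == 0 and s == s[:p] * (len(s) // p):
            return p
    return len(s)


@dataclass(frozen=True)
class STRLocus:
    """A maximal tandem repeat locus on the canonical genome.

    ``position`` is 1-based; ``unit`` is stored as written in the reference
    (its canonical form — lexicographically least rotation — is available via
    :meth:`canonical_unit`).  ``copy_min``/``copy_max`` are the observed
    bounds (equal to ``ref_copies`` until reads are counted); ``support``
    maps observed copy number to the number of supporting reads.
    """

    position: int
    unit: str
    copy_min: int | None
    copy_max: int | None
    ref_copies: int
    support: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position < 1 or not self.unit:
            raise ValueError("position must be >= 1 and unit non-empty")
        if (
            self.copy_min is not None
            and self.copy_max is not None
            and self.copy_min > self.copy_max
        ):
            raise ValueError("copy_min must be <= copy_max")

    @property
    def callable(self) -> bool:
        return self.copy_min is not None

    @property
    def is_cnv(self) -> bool:
        return self.callable and self.copy_min != self.copy_max

    def canonical_unit(self) -> str:
        return _least_rotation(self.unit)


def find_str_loci(
    seq: str,
    min_unit: int = 1,
    max_unit: int = 6,
    min_copies: Mapping[int, int] | None = None,
) -> list[STRLocus]:
    """All maximal tandem runs with unit length in [min_unit, max_unit].

    A run is reported once, at its leftmost full-unit start, with the copy
    count of whole units it contains; runs whose unit is itself periodic are
    suppressed so a run of 12 A's is ``[A]12``, never ``[AA]6``.  Copy-number
    thresholds default to >=6 for homopolymers and >=3 for units of 2-6 bp.
    """
    thresholds = dict(DEFAULT_MIN_COPIES)
    if min_copies:
        thresholds.update(min_copies)
    if not seq:
        raise ValueError("sequence must be non-empty")
    loci: list[STRLocus] = []
    n = len(seq)
    for u in range(min_unit, max_unit + 1):
        i = u
        run_start = u  # first index where seq[i] == seq[i-u] run begins
        while i <= n:
            if i < n and seq[i] == seq[i - u]:
                i += 1
                continue
            # run of matches is [run_start, i); repeat region [run_start-u, i)
            if i > run_start:
                region_start = run_start - u
                copies = (i - run_start) // u + 1
                unit = seq[region_start : region_start + u]
                if copies >= thresholds.get(u, 3) and _minimal_period(unit) == u:
                    loci.append(
                        STRLocus(
                            position=region_start + 1,
                            unit=unit,
                            copy_min=copies,
                            copy_max=copies,
                            ref_copies=copies,
                        )
                    )
            i += 1
            run_start = i
    loci.sort(key=lambda l: (l.position, len(l.unit)))
    return loci


def _spans(aln: ReadAlignment, start: int, end: int) -> bool:
    """True if a single alignment block's reference interval covers [start, end)."""
    n = aln.ref_length or None
    for _, (qs, qe) in aln.blocks:
        if qs <= start and end <= qe:
            return True
        if n and qs <= start + n and end + n <= qe:
            return True
    return False


def _locate(read: str, probe: str, max_edits: int) -> list[tuple[int, int]]:
    """(start, end) occurrences of probe in read, exact first, else edlib."""
    out = []
    start = read.find(probe)
    while start != -1:
        out.append((start, start + len(probe)))
        start = read.find(probe, start + 1)
    if out or max_edits == 0:
        return out
    res = edlib.align(probe, read, mode="HW", task="locations", k=max_edits)
    if res["editDistance"] == -1:
        return []
    return [(s, e + 1) for s, e in res["locations"]]


def _count_copies(segment: str, unit: str) -> int | None:
    u = len(unit)
    if len(segment) % u == 0 and segment == unit * (len(segment) // u):
        return len(segment) // u
    cand = round(len(segment) / u)
    if cand < 0:
        return None
    tol = max(1, round(0.2 * max(len(segment), 1)))
    d = edlib.align(segment, unit * cand, task="distance")["editDistance"]
    return cand if d <= tol else None


def str_copy_numbers(
    locus: STRLocus,
    alignments: Sequence[ReadAlignment],
    reads: Mapping[str, str],
    ref: str,
    flank: int = 10,
    min_support: int = 3,
    max_flank_edits: int = 1,
) -> STRLocus:
    """Count repeat-unit copies per spanning read and call the CNV range.

    For each alignment spanning the locus with ``flank`` anchored bases on
    both sides, the two flanking reference sequences are located in the read
    (exact match, falling back to <= ``max_flank_edits`` edits) and the unit
    copies between them are counted.  Copy numbers supported by at least
    ``min_support`` reads define ``copy_min``/``copy_max``; a locus with no
    surviving observation is returned uncallable (copy bounds None).
    """
    u = len(locus.unit)
    start0 = locus.position - 1
    end0 = start0 + u * locus.ref_copies
    if start0 < flank or end0 + flank > len(ref):
        raise ValueError("locus too close to the sequence end for the flank size")
    left = ref[start0 - flank : start0]
    right = ref[end0 : end0 + flank]
    expected_gap = u * locus.ref_copies
    counts: Counter[int] = Counter()
    for aln in alignments:
        if aln.is_empty or not _spans(aln, start0 - flank, end0 + flank):
            continue
        seq = reads.get(aln.read_id)
        if seq is None:
            continue
        if aln.strand == "-":
            seq = reverse_complement(seq)
        lhits = _locate(seq, left, max_flank_edits)
        rhits = _locate(seq, right, max_flank_edits)
        best: tuple[int, int, int] | None = None
        for ls, le in lhits:
            for rs, re_ in rhits:
                if rs < le:
                    continue
                gap = rs - le
                dev = abs(gap - expected_gap)
                if dev > expected_gap + 5 * u:
                    continue
                if best is None or dev < best[0]:
                    best = (dev, le, rs)
        if best is None:
            continue
        copies = _count_copies(seq[best[1] : best[2]], locus.unit)
        if copies is not None:
            counts[copies] += 1
    supported = sorted(c for c, k in counts.items() if k >= min_support)
    if not supported:
        return replace(locus, copy_min=None, copy_max=None, support=dict(counts))
    return replace(
        locus,
        copy_min=supported[0],
        copy_max=supported[-1],
        support=dict(counts),
    )


_NOTATION_RE = re.compile(r"^(\d+)\[([ACGT]+)\](\d+)(?:-(\d+))?$")


def format_str_notation(locus: STRLocus) -> str:
    """Render ``pos[unit]min-max`` (single number when min == max)."""
    if not locus.callable:
        raise ValueError("cannot format an uncallable locus")
    if locus.copy_min == locus.copy_max:
        return f"{locus.position}[{locus.unit}]{locus.copy_min}"
    return f"{locus.position}[{locus.unit}]{locus.copy_min}-{locus.copy_max}"


def parse_str_notation(text: str) -> STRLocus:
    """Parse ``pos[unit]min-max`` text (subscript underscores are flattened)."""
    flat = text.strip().replace("_", "")
    m = _NOTATION_RE.match(flat)
    if not m:
        raise STRNotationError(f"malformed STR descriptor: {text!r}")
    pos, unit, cmin, cmax = m.groups()
    lo = int(cmin)
    hi = int(cmax) if cmax is not None else lo
    if lo > hi:
        raise STRNotationError(f"copy range reversed in {text!r}")
    return STRLocus(
        position=int(pos), unit=unit, copy_min=lo, copy_max=hi, ref_copies=lo
    )
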