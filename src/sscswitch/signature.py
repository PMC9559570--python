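"""Junction-signature screening and chimeric-assembly detection.

Rice plastomes carry highly conserved 24-nt sequences across the IR1-SSC
boundary that differ between the two SSC orientations: the last 12 nt of IR1
followed by either the forward-SSC start (SSC-F) or the reverse-complemented
SSC end (SSC-R).  Matching these motifs classifies an assembly's junction
type without alignment; comparing the junction type with the orientation of
the SSC *body* (by local alignment against a reference SSC) flags chimeric
assemblies whose junction and body derive from different haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from Bio.Seq import reverse_complement

from .structure import (
    CircularGenome,
    HspScoring,
    QuadripartiteStructure,
    local_alignment_score,
)

__all__ = [
    "MOTIF_F",
    "MOTIF_R",
    "MOTIF_IR1_END",
    "MOTIF_SSC_F_START",
    "MOTIF_SSC_R_START",
    "SignatureVerdict",
    "ChimeraVerdict",
    "screen_junction_signature",
    "call_chimera",
]

# Conserved rice IR1-SSC junction signatures (12 nt of IR1 + 12 nt of SSC/ssc)
MOTIF_IR1_END = "TGGAAAAAATCG"
MOTIF_SSC_F_START = "GCAAATAGGAAA"
MOTIF_SSC_R_START = "CGGAAAACCGAA"
MOTIF_F = MOTIF_IR1_END + MOTIF_SSC_F_START
MOTIF_R = MOTIF_IR1_END + MOTIF_SSC_R_START


@dataclass(frozen=True)
class SignatureVerdict:
    junction_type: Literal["F", "R", "unknown"]
    motif: str | None
    position: int | None  # 1-based start of the match on the reported strand
    strand: Literal["+", "-"] | None
    mismatches: int | None


@dataclass(frozen=True)
class ChimeraVerdict:
    junction_type: Literal["F", "R", "unknown"]
    body_orientation: Literal["F", "R", "unknown"]
    is_chimeric: bool
    body_score_margin: float


def _scan_strand(seq: str, motif: str, max_mismatch: int, circular: bool) -> list[tuple[int, int]]:
    """(0-based position, mismatches) of motif hits on one strand."""
    m = len(motif)
    target = seq + seq[: m - 1] if circular and len(seq) >= m else seq
    if len(target) < m:
        return []
    if max_mismatch == 0:
        hits = []
        start = target.find(motif)
        while start != -1:
            if start < len(seq):
                hits.append((start, 0))
            start = target.find(motif, start + 1)
        return hits
    sv = np.frombuffer(target.encode("ascii"), dtype=np.uint8)
    mv = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(sv, m)
    mism = (windows != mv).sum(axis=1)
    return [
        (int(i), int(mism[i]))
        for i in np.flatnonzero(mism <= max_mismatch)
        if i < len(seq)
    ]


def screen_junction_signature(
    assembly: CircularGenome,
    motif_f: str = MOTIF_F,
    motif_r: str = MOTIF_R,
    max_mismatch: int = 0,
) -> SignatureVerdict:
    """Classify an assembly as SSC-F or SSC-R by its junction signature.

    Both strands are scanned (circularly) for each motif with up to
    ``max_mismatch`` mismatches.  If only one motif type occurs anywhere, that
    is the verdict.  A coherent quadripartite genome necessarily shows the
    opposite motif on its opposite strand (the SSC-IR2 junction read in
    reverse), so when both types are found the verdict is read from the
    presented (plus) strand — i.e. relative to the LSC orientation in which
    the assembly was submitted.  Anything else is ``unknown``.
    """
    if len(motif_f) != len(motif_r):
        raise ValueError("motifs must have equal length")
    minus = reverse_complement(assembly.seq)
    hits: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for jtype, motif in (("F", motif_f), ("R", motif_r)):
        hits[(jtype, "+")] = _scan_strand(assembly.seq, motif, max_mismatch, assembly.circular)
        hits[(jtype, "-")] = _scan_strand(minus, motif, max_mismatch, assembly.circular)

    types = {t for (t, _), h in hits.items() if h}
    if types == {"F"}:
        return SignatureVerdict("F", motif_f, *_first(hits, "F"))
    if types == {"R"}:
        return SignatureVerdict("R", motif_r, *_first(hits, "R"))
    if types == {"F", "R"}:
        plus_types = {t for t in "FR" if hits[(t, "+")]}
        if len(plus_types) == 1:
            t = plus_types.pop()
            pos, mm = hits[(t, "+")][0]
            return SignatureVerdict(t, motif_f if t == "F" else motif_r, pos + 1, "+", mm)
    return SignatureVerdict("unknown", None, None, None, None)


def _first(hits, jtype):
    for strand in "+-":
        h = hits[(jtype, strand)]
        if h:
            return h[0][0] + 1, strand, h[0][1]
    raise AssertionError


def call_chimera(
    assembly: CircularGenome,
    structure: QuadripartiteStructure,
    ref_ssc: str,
    min_margin_frac: float = 0.10,
    scoring: HspScoring | None = None,
    motif_f: str = MOTIF_F,
    motif_r: str = MOTIF_R,
    max_mismatch: int = 0,
) -> ChimeraVerdict:
    """Compare junction type against SSC-body orientation.

    The body orientation is the strand of the higher-scoring local alignment
    of the assembly's SSC region against ``ref_ssc`` (a reference SSC of
    known forward orientation); the winner must lead by at least
    ``min_margin_frac`` of its score, otherwise the body is ``unknown``.  The
    assembly is chimeric iff junction type and body orientation are both
    known and disagree — the pattern seen when an SSC was assembled from
    reads of both orientation haplotypes.
    """
    if not ref_ssc:
        raise ValueError("ref_ssc must be non-empty")
    if structure.rotation != 0:
        raise ValueError("structure must be canonical (rotation 0)")
    structure.validate_for(assembly)
    ssc = assembly.seq[slice(*structure.ssc)]
    score_f = local_alignment_score(ssc, ref_ssc, scoring)
    score_r = local_alignment_score(ssc, reverse_complement(ref_ssc), scoring)
    margin = abs(score_f - score_r)
    winner = max(score_f, score_r)
    if winner <= 0 or margin < min_margin_frac * winner:
        body: Literal["F", "R", "unknown"] = "unknown"
    else:
        body = "F" if score_f > score_r else "R"
    junction = screen_junction_signature(assembly, motif_f, motif_r, max_mismatch)
    is_chimeric = (
        junction.junction_type != "unknown"
        and body != "unknown"
        and junction.junction_type != body
    )
    return ChimeraVerdict(junction.junction_type, body, is_chimeric, margin)
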