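"""Junction-read classification and SSC-orientation statistics.

Long reads that span an entire IR copy plus flanking single-copy sequence on
both sides ("junction reads") phase the orientation of the SSC: a read that
aligns across LSC-IR1-SSC supports the forward (SSC-F) haplotype, one that
aligns across LSC-IR1-ssc supports the reverse (SSC-R) haplotype.  The
classification rule follows the validation criteria used for plastome
structural variants: a haplotype wins when the read aligns with more than 90%
of its length, covers 100% of IR1, and carries two >=200-bp overhangs aligned
into LSC and SSC/ssc at the 5' and 3' ends of IR1.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import edlib
import numpy as np
import pysam
from Bio.Seq import reverse_complement
from statsmodels.stats.proportion import proportion_confint

from .structure import CircularGenome, QuadripartiteStructure

logger = logging.getLogger(__name__)

__all__ = [
    "ReadAlignment",
    "JunctionCall",
    "OrientationReport",
    "ClassifyParams",
    "ReferenceIndex",
    "map_read",
    "import_alignments",
    "classify_junction_read",
    "classify_reads",
    "summarize_orientation",
]

Block = tuple[tuple[int, int], tuple[int, int]]  # (read interval, ref interval)


@dataclass(frozen=True)
class ReadAlignment:
    """Block-structured alignment of one read against one reference.

    Blocks pair 0-based half-open read intervals (in the orientation given by
    ``strand``) with reference intervals; for circular references the
    reference coordinates may run into the doubled range [0, 2n) so that
    origin-crossing alignments stay monotone.
    """

    read_id: str
    ref_id: str
    strand: Literal["+", "-"]
    blocks: tuple[Block, ...]
    identity: float
    aligned_read_fraction: float
    read_length: int
    ref_length: int

    @property
    def is_empty(self) -> bool:
        return not self.blocks

    @property
    def aligned_read_bases(self) -> int:
        return sum(re - rs for (rs, re), _ in self.blocks)


@dataclass(frozen=True)
class JunctionCall:
    """Per-read SSC-orientation call with the supporting junction metrics."""

    read_id: str
    label: Literal["forward", "reverse", "ambiguous", "non_junction"]
    ir_coverage: float
    left_overhang: int
    right_overhang: int
    winning_ref: Literal["F", "R", "none"]


@dataclass(frozen=True)
class OrientationReport:
    """Counts and proportions of SSC-F vs SSC-R junction reads.

    ``ratio_printed`` divides the two proportions after rounding each to two
    decimals (the convention used when quoting e.g. 0.82 = 0.45/0.55);
    ``ratio`` keeps full precision.  The confidence interval is a Wilson score
    interval for ``prop_forward``.
    """

    n_forward: int
    n_reverse: int
    n_ambiguous: int
    n_non_junction: int
    prop_forward: float | None
    prop_reverse: float | None
    ratio: float | None
    ratio_printed: float | None
    ci_low: float | None
    ci_high: float | None
    ci_level: float = 0.95
    ci_method: str = "wilson"

    @property
    def n_classified(self) -> int:
        return self.n_forward + self.n_reverse


@dataclass(frozen=True)
class ClassifyParams:
    """Thresholds of the junction-read classification rule.

    ``min_read_frac`` is strict ("more than 90% of their lengths");
    ``min_ir_cover`` of 1.0 demands every IR1 base covered; ``min_overhang``
    is the flanking requirement on both sides of IR1.  ``min_read_len`` is an
    optional pre-filter (the full-scale workflow used >20 kb subreads; scaled
    synthetic data leaves it off).  ``use_ir2`` extends the same rule to the
    SSC-IR2-LSC junction, disabled by default.
    """

    min_read_frac: float = 0.90
    min_ir_cover: float = 1.00
    min_overhang: int = 200
    min_read_len: int | None = None
    use_ir2: bool = False
    k: int = 15
    min_chain_anchors: int = 3
    band: int = 100

    @classmethod
    def paper_preset(cls) -> "ClassifyParams":
        return cls(min_read_len=20_000)


# ---------------------------------------------------------------------------
# mapping


class ReferenceIndex:
    """Exact k-mer index of a (circular) reference for anchor seeding."""

    def __init__(self, ref: CircularGenome, k: int = 15):
        self.ref = ref
        self.k = k
        n = len(ref)
        self.n = n
        self.doubled = ref.seq + ref.seq if ref.circular else ref.seq
        index: dict[str, list[int]] = defaultdict(list)
        limit = n if ref.circular else n - k + 1
        for i in range(limit):
            index[self.doubled[i : i + k]].append(i)
        self.index = dict(index)

    def anchors(self, read: str, max_occ: int = 8) -> list[tuple[int, int]]:
        """(read_pos, ref_pos mod n) pairs of exact k-mer matches."""
        k = self.k
        out: list[tuple[int, int]] = []
        for r in range(len(read) - k + 1):
            hits = self.index.get(read[r : r + k])
            if hits is None or len(hits) > max_occ:
                continue
            for p in hits:
                out.append((r, p))
        return out


def _cluster_anchors(
    anchors: list[tuple[int, int]], n: int, band: int, max_gap: int = 200
) -> list[list[tuple[int, int]]]:
    """Group anchors into diagonal bands on the circle.

    The diagonal of an anchor (r, p) is (p - r) mod n; anchors of one gapless
    alignment segment share it up to indel drift within ``band``.  Clusters
    are split where consecutive anchors are more than ``max_gap`` bp apart on
    the read: distinct repeat copies (e.g. IR1 and IR2 around an unaligned
    SSC) can share a diagonal, and a block must not bridge such a gap.
    """
    if not anchors:
        return []
    keyed = sorted(((p - r) % n, r, p) for r, p in anchors)
    clusters: list[list[tuple[int, int, int]]] = [[keyed[0]]]
    for item in keyed[1:]:
        if item[0] - clusters[-1][-1][0] <= band:
            clusters[-1].append(item)
        else:
            clusters.append([item])
    # diagonals are circular: merge the first and last cluster across the wrap
    if len(clusters) > 1 and (keyed[0][0] + n) - clusters[-1][-1][0] <= band:
        clusters[0] = clusters.pop() + clusters[0]
    out: list[list[tuple[int, int]]] = []
    for cl in clusters:
        by_read = sorted((r, p) for _, r, p in cl)
        piece = [by_read[0]]
        for r, p in by_read[1:]:
            if r - piece[-1][0] > max_gap:
                out.append(piece)
                piece = []
            piece.append((r, p))
        out.append(piece)
    return out


def _extend_exact(
    read: str, doubled: str, rs: int, re_: int, qs: int, qe: int
) -> tuple[int, int, int, int]:
    while rs > 0 and qs > 0 and read[rs - 1] == doubled[qs - 1]:
        rs -= 1
        qs -= 1
    while re_ < len(read) and qe < len(doubled) and read[re_] == doubled[qe]:
        re_ += 1
        qe += 1
    return rs, re_, qs, qe


def _block_identity(read_seg: str, ref_seg: str) -> float:
    if not read_seg or not ref_seg:
        return 0.0
    dist = edlib.align(read_seg, ref_seg, task="distance")["editDistance"]
    return 1.0 - dist / max(len(read_seg), len(ref_seg))


def _empty_alignment(read_id: str, ref: CircularGenome, read_len: int) -> ReadAlignment:
    return ReadAlignment(
        read_id=read_id, ref_id=ref.id, strand="+", blocks=(),
        identity=0.0, aligned_read_fraction=0.0,
        read_length=read_len, ref_length=len(ref),
    )


def map_read(
    read: str,
    ref: CircularGenome | ReferenceIndex,
    read_id: str = "read",
    k: int = 15,
    min_chain_anchors: int = 3,
    band: int = 100,
) -> ReadAlignment:
    """Map a read against a circular reference by k-mer anchor chaining.

    Exact k-mers are seeded against the reference treated circularly, anchors
    are clustered on diagonal bands, the strand with more anchors wins, and
    each cluster becomes an alignment block whose ends are extended by exact
    matching; per-block identity comes from an edit-distance alignment of the
    paired segments.  Deterministic for fixed inputs; a read with no anchors
    yields an empty alignment (aligned_read_fraction 0), not an error.
    """
    idx = ref if isinstance(ref, ReferenceIndex) else ReferenceIndex(ref, k)
    if len(read) < idx.k:
        return _empty_alignment(read_id, idx.ref, len(read))

    by_strand = {}
    for strand, oriented in (("+", read), ("-", reverse_complement(read))):
        by_strand[strand] = (oriented, idx.anchors(oriented))
    strand = max(by_strand, key=lambda s: len(by_strand[s][1]))
    oriented, anchors = by_strand[strand]
    if len(anchors) < min_chain_anchors:
        return _empty_alignment(read_id, idx.ref, len(read))

    clusters = [
        cl for cl in _cluster_anchors(anchors, idx.n, band)
        if len(cl) >= min_chain_anchors
    ]
    if not clusters:
        return _empty_alignment(read_id, idx.ref, len(read))

    # Greedy chain selection: biggest cluster first, reject read-overlapping ones.
    clusters.sort(key=len, reverse=True)
    chosen: list[tuple[int, int, int, int]] = []  # (rs, re, qs, qe)
    for cl in clusters:
        rs = min(r for r, _ in cl)
        re_ = max(r for r, _ in cl) + idx.k
        diag = (cl[0][1] - cl[0][0]) % idx.n
        qs = rs + diag
        qe = re_ + diag
        if qe > len(idx.doubled):
            qs -= idx.n
            qe -= idx.n
        rs, re_, qs, qe = _extend_exact(oriented, idx.doubled, rs, re_, qs, qe)
        if any(not (re_ <= ors + 20 or rs >= ore - 20) for ors, ore, *_ in chosen):
            continue
        chosen.append((rs, re_, qs, qe))
    chosen.sort()

    blocks: list[Block] = []
    ident_num = 0.0
    ident_den = 0
    for rs, re_, qs, qe in chosen:
        blocks.append(((rs, re_), (qs, qe)))
        ident = _block_identity(oriented[rs:re_], idx.doubled[qs:qe])
        ident_num += ident * (re_ - rs)
        ident_den += re_ - rs
    aligned = sum(re_ - rs for (rs, re_), _ in blocks)
    return ReadAlignment(
        read_id=read_id, ref_id=idx.ref.id, strand=strand, blocks=tuple(blocks),
        identity=ident_num / ident_den if ident_den else 0.0,
        aligned_read_fraction=min(1.0, aligned / len(read)),
        read_length=len(read), ref_length=idx.n,
    )


# ---------------------------------------------------------------------------
# SAM import


_CIGAR_CONSUMES_READ = {0, 1, 4, 7, 8}  # M, I, S, =, X
_CIGAR_CONSUMES_REF = {0, 2, 3, 7, 8}  # M, D, N, =, X


def _record_blocks(rec: pysam.AlignedSegment) -> list[Block]:
    blocks: list[Block] = []
    qpos = 0
    rpos = rec.reference_start
    if rec.cigartuples is None:
        raise ValueError(f"record {rec.query_name!r} has no CIGAR")
    for op, length in rec.cigartuples:
        if op in (0, 7, 8):  # aligned columns
            blocks.append(((qpos, qpos + length), (rpos, rpos + length)))
        if op in _CIGAR_CONSUMES_READ and op != 4:
            qpos += length
        elif op == 4:
            qpos += length
        if op in _CIGAR_CONSUMES_REF:
            rpos += length
    # merge read-adjacent blocks separated only by ref gaps and vice versa
    merged: list[Block] = []
    for b in blocks:
        if merged and merged[-1][0][1] == b[0][0] and merged[-1][1][1] == b[1][0]:
            (rs, _), (qs, _) = merged[-1]
            merged[-1] = ((rs, b[0][1]), (qs, b[1][1]))
        else:
            merged.append(b)
    return merged


def import_alignments(
    source, ref_names: Iterable[str] | None = None
) -> list[ReadAlignment]:
    """Read SAM records and merge them into per-(read, reference) alignments.

    Primary and supplementary records are combined into one block list;
    secondary and unmapped records are dropped.  Soft/hard-clipped bases count
    toward read length but not toward ``aligned_read_fraction``.  Records
    naming a reference outside ``ref_names`` (when given) are skipped with a
    logged warning.
    """
    wanted = set(ref_names) if ref_names is not None else None
    grouped: dict[tuple[str, str], list[pysam.AlignedSegment]] = defaultdict(list)
    ref_lens: dict[str, int] = {}
    with pysam.AlignmentFile(source, "r", check_sq=False) as fh:
        for name, length in zip(fh.references, fh.lengths):
            ref_lens[name] = length
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            if wanted is not None and rec.reference_name not in wanted:
                logger.warning(
                    "skipping record %r: unknown reference %r",
                    rec.query_name, rec.reference_name,
                )
                continue
            grouped[(rec.query_name, rec.reference_name)].append(rec)

    out: list[ReadAlignment] = []
    for (read_id, ref_id), recs in grouped.items():
        blocks: list[Block] = []
        nm = 0
        has_nm = True
        read_len = 0
        primary_strand = "+"
        for rec in recs:
            try:
                blocks.extend(_record_blocks(rec))
            except ValueError as exc:
                raise ValueError(f"malformed record for read {read_id!r}: {exc}") from exc
            read_len = max(read_len, rec.infer_read_length() or 0)
            if not rec.is_supplementary:
                primary_strand = "-" if rec.is_reverse else "+"
            if rec.has_tag("NM"):
                nm += int(rec.get_tag("NM"))
            else:
                has_nm = False
        blocks.sort()
        aligned = sum(re - rs for (rs, re), _ in blocks)
        identity = 1.0 - nm / aligned if (has_nm and aligned) else 1.0
        out.append(
            ReadAlignment(
                read_id=read_id, ref_id=ref_id, strand=primary_strand,
                blocks=tuple(blocks),
                identity=max(0.0, identity),
                aligned_read_fraction=min(1.0, aligned / read_len) if read_len else 0.0,
                read_length=read_len, ref_length=ref_lens.get(ref_id, 0),
            )
        )
    return out


# ---------------------------------------------------------------------------
# junction classification


def _coverage_array(aln: ReadAlignment, n: int) -> np.ndarray:
    cov = np.zeros(n, dtype=bool)
    for _, (qs, qe) in aln.blocks:
        s, e = qs % n, qs % n + (qe - qs)
        if e <= n:
            cov[s:e] = True
        else:
            cov[s:] = True
            cov[: e - n] = True
    return cov


def _junction_metrics(
    aln: ReadAlignment,
    ir: tuple[int, int],
    left_region_len: int,
    right_region_len: int,
    n: int,
) -> tuple[float, int, int]:
    """IR coverage plus contiguous aligned overhangs flanking the IR.

    Overhangs count covered bases walking outward from the IR boundaries into
    the neighbouring single-copy regions (circularly), capped at those
    regions' lengths.
    """
    if aln.is_empty:
        return 0.0, 0, 0
    cov = _coverage_array(aln, n)
    s, e = ir
    ir_cov = float(cov[s:e].mean())
    left = 0
    pos = (s - 1) % n
    while left < left_region_len and cov[pos]:
        left += 1
        pos = (pos - 1) % n
    right = 0
    pos = e % n
    while right < right_region_len and cov[pos]:
        right += 1
        pos = (pos + 1) % n
    return ir_cov, left, right


def _satisfies(
    aln: ReadAlignment,
    structure: QuadripartiteStructure,
    params: ClassifyParams,
) -> tuple[bool, float, int, int]:
    n = structure.total_len
    ir_cov, left, right = _junction_metrics(
        aln, structure.ir1, structure.lsc_len, structure.ssc_len, n
    )
    ok = (
        aln.aligned_read_fraction > params.min_read_frac
        and ir_cov >= params.min_ir_cover
        and left >= params.min_overhang
        and right >= params.min_overhang
    )
    if params.use_ir2 and not ok:
        ir_cov2, left2, right2 = _junction_metrics(
            aln, structure.ir2, structure.ssc_len, structure.lsc_len, n
        )
        if (
            aln.aligned_read_fraction > params.min_read_frac
            and ir_cov2 >= params.min_ir_cover
            and left2 >= params.min_overhang
            and right2 >= params.min_overhang
        ):
            return True, ir_cov2, left2, right2
    return ok, ir_cov, left, right


def classify_junction_read(
    align_f: ReadAlignment,
    align_r: ReadAlignment,
    structure: QuadripartiteStructure,
    params: ClassifyParams | None = None,
) -> JunctionCall:
    """Label one read as forward / reverse / ambiguous / non_junction.

    Both alignments must belong to the same read (against the SSC-F and SSC-R
    haplotype references respectively).  A haplotype satisfies the junction
    criteria iff the read aligns with more than ``min_read_frac`` of its
    length, covers ``min_ir_cover`` of IR1, and has ``min_overhang`` aligned
    bases into LSC and into SSC/ssc immediately flanking IR1.
    """
    params = params or ClassifyParams()
    if align_f.read_id != align_r.read_id:
        raise ValueError("alignments refer to different reads")
    if params.min_read_len is not None and align_f.read_length < params.min_read_len:
        return JunctionCall(align_f.read_id, "non_junction", 0.0, 0, 0, "none")
    ok_f, cov_f, l_f, r_f = _satisfies(align_f, structure, params)
    ok_r, cov_r, l_r, r_r = _satisfies(align_r, structure, params)
    if ok_f and not ok_r:
        return JunctionCall(align_f.read_id, "forward", cov_f, l_f, r_f, "F")
    if ok_r and not ok_f:
        return JunctionCall(align_f.read_id, "reverse", cov_r, l_r, r_r, "R")
    if ok_f and ok_r:
        return JunctionCall(align_f.read_id, "ambiguous", cov_f, l_f, r_f, "none")
    cov, left, right = max((cov_f, l_f, r_f), (cov_r, l_r, r_r))
    return JunctionCall(align_f.read_id, "non_junction", cov, left, right, "none")


def classify_reads(
    reads: Sequence[tuple[str, str]],
    ref_f: CircularGenome,
    ref_r: CircularGenome,
    structure: QuadripartiteStructure,
    params: ClassifyParams | None = None,
) -> list[JunctionCall]:
    """Map (read_id, sequence) pairs to both haplotypes and classify each."""
    params = params or ClassifyParams()
    idx_f = ReferenceIndex(ref_f, params.k)
    idx_r = ReferenceIndex(ref_r, params.k)
    calls = []
    for read_id, seq in reads:
        aln_f = map_read(seq, idx_f, read_id, params.k, params.min_chain_anchors, params.band)
        aln_r = map_read(seq, idx_r, read_id, params.k, params.min_chain_anchors, params.band)
        calls.append(classify_junction_read(aln_f, aln_r, structure, params))
    return calls


def summarize_orientation(
    calls: Iterable[JunctionCall] | None = None,
    ci_level: float = 0.95,
    counts: tuple[int, int] | None = None,
) -> OrientationReport:
    """Aggregate junction calls into the SSC-F/SSC-R orientation report.

    ``counts`` may be given directly as (n_forward, n_reverse) instead of a
    call list.  With no classified reads the proportions and ratio are None
    rather than raising.
    """
    n_amb = n_non = 0
    if counts is not None:
        nf, nr = counts
    else:
        nf = nr = 0
        for c in calls or ():
            if c.label == "forward":
                nf += 1
            elif c.label == "reverse":
                nr += 1
            elif c.label == "ambiguous":
                n_amb += 1
            else:
                n_non += 1
    total = nf + nr
    if total == 0:
        return OrientationReport(nf, nr, n_amb, n_non, None, None, None, None,
                                 None, None, ci_level)
    pf = nf / total
    pr = nr / total
    ratio = pf / pr if nr else None
    pf2, pr2 = round(pf, 2), round(pr, 2)
    ratio_printed = round(pf2 / pr2, 2) if pr2 else None
    lo, hi = proportion_confint(nf, total, alpha=1 - ci_level, method="wilson")
    return OrientationReport(
        nf, nr, n_amb, n_non, pf, pr, ratio, ratio_printed,
        float(lo), float(hi), ci_level,
    )
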