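"""Three-pass conversion-aware alignment for bisulfite-converted RNA reads.

Bisulfite chemistry converts unmethylated C to T, so a read T over a
reference C is *not* a mismatch (the reverse, read C over reference T,
is).  Alignment is an exhaustive end-to-end scan of every offset of the
mini-reference — both genome strands are searched but only in the
transcript-sense (C->T) conversion space, as for a directional stranded
library — with Hamming-style scoring, no indels, and a mismatch ceiling
(default 2).  Ties at the best score are reported as ambiguous, matching
aligners that emit ambiguous reads to a separate stream.

Pass 1 aligns end-to-end to the genome.  Pass 2 retries pass-1 failures
after clipping the 3 terminal bases — the post-transcriptional tRNA CCA
tail, absent from the genome.  Pass 3 aligns the remaining unaligned
reads to a splice-junction library and converts hits back to genomic
coordinates, storing the spanned intron as a cigar D op.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pysam

from .reference import ReferenceBundle, JunctionLibrary, reverse_complement

_C = ord("C")
_T = ord("T")
_N = ord("N")


@dataclass
class AlignParams:
    max_mismatch: int = 2  # "-n 2": up to two non-conversion mismatches
    min_length: int = 20   # reads shorter than this after CCA clipping are discarded

    def __post_init__(self):
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")


@dataclass
class AlignmentRecord:
    read_id: str
    contig: str
    start: int  # leftmost genomic base, 0-based
    strand: str
    cigar: tuple[tuple[str, int], ...]  # ops over {M, D}; D = spanned intron
    bs_mismatches: int
    pass_label: int
    clipped_tail: int
    seq: str  # the (possibly clipped) read sequence actually aligned, sense space

    @property
    def aligned_length(self) -> int:
        return sum(n for op, n in self.cigar if op == "M")

    def aligned_pairs(self, bundle: ReferenceBundle) -> list[tuple[int, str, int, str]]:
        """(read_pos, contig, genomic_pos, sense reference base) per aligned
        base.  For minus-strand hits the read runs right-to-left along the
        genome and the sense base is the complement of the contig base."""
        contig_seq = bundle.contigs[self.contig]
        gpositions: list[int] = []
        g = self.start
        for op, n in self.cigar:
            if op == "M":
                gpositions.extend(range(g, g + n))
                g += n
            elif op == "D":
                g += n
            else:
                raise ValueError(f"unsupported cigar op {op}")
        total = len(gpositions)
        pairs = []
        for i, gpos in enumerate(gpositions):
            if self.strand == "+":
                read_pos = i
                base = contig_seq[gpos]
            else:
                read_pos = total - 1 - i
                base = reverse_complement(contig_seq[gpos])
            pairs.append((read_pos, self.contig, gpos, base))
        return pairs


@dataclass
class AlignmentOutcome:
    read_id: str
    outcome_class: str  # unique | ambiguous | unaligned | discarded_short
    record: AlignmentRecord | None = None


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def bs_match_score(read: str, ref_window: str) -> int:
    """Bisulfite mismatch count between equal-length read and reference
    window: reference C matched by read T is a conversion event, not a
    mismatch; read C over reference T *is* a mismatch; N never matches."""
    if len(read) != len(ref_window):
        raise ValueError("read and reference window lengths differ")
    r = _encode(read)
    w = _encode(ref_window)
    match = ((w == r) | ((w == _C) & (r == _T))) & (r != _N) & (w != _N)
    return int(len(r) - match.sum())


@dataclass
class _Segment:
    """One linear search space: a contig orientation or a junction entry."""
    name: str       # contig name or junction id
    strand: str     # genomic strand of a hit found in this segment
    arr: np.ndarray
    is_junction: bool = False

    def genomic_start(self, offset: int, read_len: int) -> int:
        if self.strand == "+" or self.is_junction:
            return offset
        return len(self.arr) - offset - read_len


def _genome_segments(bundle: ReferenceBundle) -> list[_Segment]:
    segs = []
    for name, seq in bundle.contigs.items():
        segs.append(_Segment(name, "+", _encode(seq)))
        segs.append(_Segment(name, "-", _encode(reverse_complement(seq))))
    return segs


def _junction_segments(library: JunctionLibrary) -> list[_Segment]:
    return [
        _Segment(e.junction_id, "+", _encode(e.sequence), is_junction=True)
        for e in library.entries
    ]


def _scan(
    reads: Sequence[tuple[str, str]],
    segments: list[_Segment],
    params: AlignParams,
    chunk: int = 512,
) -> list[tuple[int, list[tuple[_Segment, int]]]]:
    """For each read: (best mismatch count, all loci achieving it).

    Vectorized over reads of equal length; loci capped at 8 per read
    (enough to decide unique vs ambiguous).
    """
    results: list[tuple[int, list]] = [(10**9, []) for _ in reads]
    by_len: dict[int, list[int]] = {}
    for i, (_rid, seq) in enumerate(reads):
        by_len.setdefault(len(seq), []).append(i)
    for L, idxs in by_len.items():
        mat = np.stack([_encode(reads[i][1]) for i in idxs])
        best = np.full(len(idxs), 10**9, dtype=np.int64)
        loci: list[list] = [[] for _ in idxs]
        for seg in segments:
            if len(seg.arr) < L:
                continue
            win = np.lib.stride_tricks.sliding_window_view(seg.arr, L)
            ref_ok = win != _N
            conv = win == _C
            for c0 in range(0, len(idxs), chunk):
                sub = mat[c0 : c0 + chunk]
                m = (
                    ((win[None] == sub[:, None]) | (conv[None] & (sub[:, None] == _T)))
                    & ref_ok[None]
                    & (sub[:, None] != _N)
                )
                mm = L - m.sum(axis=2)
                seg_min = mm.min(axis=1)
                for j in range(len(sub)):
                    k = c0 + j
                    if seg_min[j] > best[k]:
                        continue
                    offs = np.nonzero(mm[j] == seg_min[j])[0]
                    if seg_min[j] < best[k]:
                        best[k] = seg_min[j]
                        loci[k] = []
                    for o in offs[:8]:
                        if len(loci[k]) < 8:
                            loci[k].append((seg, int(o)))
        for k, i in enumerate(idxs):
            results[i] = (int(best[k]), loci[k])
    return results


def _make_record(
    read_id: str,
    seq: str,
    seg: _Segment,
    offset: int,
    mismatches: int,
    pass_label: int,
    clipped_tail: int,
) -> AlignmentRecord:
    L = len(seq)
    return AlignmentRecord(
        read_id=read_id,
        contig=seg.name,
        start=seg.genomic_start(offset, L),
        strand=seg.strand,
        cigar=(("M", L),),
        bs_mismatches=mismatches,
        pass_label=pass_label,
        clipped_tail=clipped_tail,
        seq=seq,
    )


def align_pass1(
    reads: Sequence[tuple[str, str]],
    bundle: ReferenceBundle,
    params: AlignParams | None = None,
    *,
    _segments: list[_Segment] | None = None,
    _pass_label: int = 1,
    _clipped: int = 0,
) -> list[AlignmentOutcome]:
    """End-to-end exhaustive alignment of (read_id, sequence) pairs to the
    genome contigs; one outcome per read."""
    params = params or AlignParams()
    if not bundle.contigs:
        raise ValueError("empty reference")
    segments = _segments if _segments is not None else _genome_segments(bundle)
    outcomes = []
    for (rid, seq), (best, loci) in zip(reads, _scan(reads, segments, params)):
        if best > params.max_mismatch or not loci:
            outcomes.append(AlignmentOutcome(rid, "unaligned"))
        elif len(loci) > 1:
            outcomes.append(AlignmentOutcome(rid, "ambiguous"))
        else:
            seg, off = loci[0]
            outcomes.append(
                AlignmentOutcome(
                    rid, "unique",
                    _make_record(rid, seq, seg, off, best, _pass_label, _clipped),
                )
            )
    return outcomes


def clip_and_realign(
    failed_reads: Sequence[tuple[str, str]],
    bundle: ReferenceBundle,
    params: AlignParams | None = None,
    clip: int = 3,
) -> list[AlignmentOutcome]:
    """Remove the last ``clip`` bases (a potential tRNA CCA tail) from
    pass-1 unaligned/ambiguous reads and realign.  Reads falling below
    ``params.min_length`` after clipping are discarded_short."""
    params = params or AlignParams()
    keep: list[tuple[str, str]] = []
    outcomes: dict[str, AlignmentOutcome] = {}
    for rid, seq in failed_reads:
        clipped = seq[:-clip] if clip else seq
        if len(clipped) < params.min_length:
            outcomes[rid] = AlignmentOutcome(rid, "discarded_short")
        else:
            keep.append((rid, clipped))
    realigned = align_pass1(
        keep, bundle, params, _pass_label=2, _clipped=clip
    )
    for out in realigned:
        outcomes[out.read_id] = out
    return [outcomes[rid] for rid, _ in failed_reads]


def convert_to_genomic(
    record: AlignmentRecord, bundle: ReferenceBundle
) -> AlignmentRecord:
    """Convert a junction-library hit back to genomic coordinates.

    The junction record's contig is a junction id and its start an offset
    within the 2*flank junction sequence.  The genomic cigar stores the
    spanned intron as a D op (abutting blocks merge into a single M).
    """
    entry = bundle.junction_library.by_id(record.contig)
    tx = bundle.transcripts[entry.transcript_id]
    L = record.aligned_length
    o = record.start
    if o + L > 2 * entry.flank_len:
        raise ValueError("aligned segment falls outside junction flanks")
    tx_start = entry.tx_junction_offset - entry.flank_len + o
    gstart, cigar = tx.interval_to_genomic(tx_start, tx_start + L)
    return AlignmentRecord(
        read_id=record.read_id,
        contig=tx.contig,
        start=gstart,
        strand=tx.strand,
        cigar=tuple(cigar),
        bs_mismatches=record.bs_mismatches,
        pass_label=3,
        clipped_tail=record.clipped_tail,
        seq=record.seq,
    )


def junction_align(
    failed_reads: Sequence[tuple[str, str]],
    bundle: ReferenceBundle,
    params: AlignParams | None = None,
) -> list[AlignmentOutcome]:
    """Align pass-2 unaligned reads to the junction library; unique hits
    that straddle the junction (>=1 nt on each flank) are converted to
    genomic records with the intron as a cigar D op."""
    params = params or AlignParams()
    segments = _junction_segments(bundle.junction_library)
    outcomes = []
    if not segments:
        return [AlignmentOutcome(rid, "unaligned") for rid, _ in failed_reads]
    for (rid, seq), (best, loci) in zip(
        failed_reads, _scan(failed_reads, segments, params)
    ):
        if best > params.max_mismatch or not loci:
            outcomes.append(AlignmentOutcome(rid, "unaligned"))
            continue
        L = len(seq)
        converted = []
        for seg, off in loci:
            entry = bundle.junction_library.by_id(seg.name)
            f = entry.flank_len
            if not (off < f < off + L):
                continue  # within one flank: already covered by genomic passes
            rec = _make_record(rid, seq, seg, off, best, 3, 0)
            converted.append(convert_to_genomic(rec, bundle))
        distinct = {(r.contig, r.start, r.strand, r.cigar) for r in converted}
        if len(distinct) == 1:
            outcomes.append(AlignmentOutcome(rid, "unique", converted[0]))
        elif len(distinct) > 1:
            outcomes.append(AlignmentOutcome(rid, "ambiguous"))
        else:
            outcomes.append(AlignmentOutcome(rid, "unaligned"))
    return outcomes


@dataclass
class AlignStats:
    per_pass: dict = field(default_factory=dict)

    def count(self, pass_name: str, outcomes: Iterable[AlignmentOutcome]) -> None:
        tally: dict[str, int] = {}
        for o in outcomes:
            tally[o.outcome_class] = tally.get(o.outcome_class, 0) + 1
        self.per_pass[pass_name] = tally


def align_reads(
    reads: Sequence[tuple[str, str]],
    bundle: ReferenceBundle,
    params: AlignParams | None = None,
) -> tuple[list[AlignmentOutcome], AlignStats]:
    """Run the full three-pass cascade; exactly one final outcome per read.

    Pass-1 unaligned *and* ambiguous reads get the CCA-clip retry; only
    pass-2 unaligned reads continue to the junction pass.
    """
    params = params or AlignParams()
    stats = AlignStats()
    final: dict[str, AlignmentOutcome] = {}

    p1 = align_pass1(reads, bundle, params)
    stats.count("pass1", p1)
    failed1 = []
    read_seq = dict(reads)
    for out in p1:
        if out.outcome_class == "unique":
            final[out.read_id] = out
        else:
            failed1.append((out.read_id, read_seq[out.read_id]))

    p2 = clip_and_realign(failed1, bundle, params)
    stats.count("pass2", p2)
    failed2 = []
    for out in p2:
        if out.outcome_class == "unaligned":
            failed2.append((out.read_id, read_seq[out.read_id][:-3]))
        else:
            final[out.read_id] = out

    p3 = junction_align(failed2, bundle, params)
    stats.count("pass3", p3)
    for out in p3:
        final[out.read_id] = out

    ordered = [final[rid] for rid, _ in reads]
    assert len(ordered) == len(reads)
    return ordered, stats


# ---------------------------------------------------------------------------
# SAM output


def write_sam(
    outcomes: Sequence[AlignmentOutcome], bundle: ReferenceBundle, path
) -> None:
    """Unique alignments as SAM.  Cigar uses M/D only (intron skips stored
    as D for methylation-extractor compatibility); custom tags: XP pass
    label, XC clipped-tail length, XB bisulfite mismatches."""
    names = list(bundle.contigs)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(bundle.contigs[n])} for n in names],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for out in outcomes:
            if out.outcome_class != "unique":
                continue
            rec = out.record
            a = pysam.AlignedSegment(sam.header)
            a.query_name = rec.read_id
            a.reference_id = names.index(rec.contig)
            a.reference_start = rec.start
            a.mapping_quality = 255
            a.flag = 16 if rec.strand == "-" else 0
            a.cigarstring = "".join(f"{n}{op}" for op, n in rec.cigar)
            a.query_sequence = (
                rec.seq if rec.strand == "+" else reverse_complement(rec.seq)
            )
            a.query_qualities = pysam.qualitystring_to_array("I" * len(rec.seq))
            a.set_tag("XP", rec.pass_label, "i")
            a.set_tag("XC", rec.clipped_tail, "i")
            a.set_tag("XB", rec.bs_mismatches, "i")
            sam.write(a)


def read_sam(path, bundle: ReferenceBundle) -> list[AlignmentRecord]:
    """Round-trip unique alignments from a SAM written by :func:`write_sam`."""
    records = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for a in sam:
            strand = "-" if a.is_reverse else "+"
            seq = a.query_sequence
            if strand == "-":
                seq = reverse_complement(seq)
            cigar = tuple(
                ({0: "M", 2: "D"}[op], n) for op, n in a.cigartuples
            )
            records.append(
                AlignmentRecord(
                    read_id=a.query_name,
                    contig=a.reference_name,
                    start=a.reference_start,
                    strand=strand,
                    cigar=cigar,
                    bs_mismatches=a.get_tag("XB"),
                    pass_label=a.get_tag("XP"),
                    clipped_tail=a.get_tag("XC"),
                    seq=seq,
                )
            )
    return records
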