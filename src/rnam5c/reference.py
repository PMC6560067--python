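"""Mini-reference data model: transcripts, genomic placement, cytosine sites.

Everything downstream (simulation, alignment, methylation extraction) works
against a :class:`ReferenceBundle` — a handful of contigs with transcripts
placed on them, annotated cytosines, and a splice-junction library built
from the multi-exon transcripts.

Conventions
-----------
* Internal alphabet is DNA: RNA input (U) is normalized to T on ingest;
  :func:`reverse_complement` restores U when the caller passed RNA.
* All coordinates are 0-based, half-open.  Biological site labels such as
  ``VTRNA1.1:C69`` are 1-based from the transcript 5' end (label index =
  transcript offset + 1).
* tRNA transcripts flagged ``has_cca_tail`` carry a post-transcriptional
  3' CCA in their stored sequence that is absent from the genome, so the
  exon blocks cover ``len(sequence) - 3`` bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BIOTYPES = {"tRNA", "vaultRNA", "mRNA", "other"}

_DNA_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_RNA_COMP = str.maketrans("ACGUNacgun", "UGCANugcan")


def normalize_seq(seq: str) -> str:
    """Uppercase and map U->T so all comparisons happen in DNA space."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str, rna: bool | None = None) -> str:
    """Watson-Crick reverse complement, preserving the input alphabet.

    DNA input yields DNA and RNA input yields RNA.  The alphabet is
    auto-detected from the presence of U; pass ``rna=True``/``False`` to
    force it (a U-free RNA string is otherwise indistinguishable from
    DNA).  Case is preserved per character.

    Raises
    ------
    ValueError
        If the sequence contains a non-nucleotide character.
    """
    is_rna = ("U" in seq.upper()) if rna is None else rna
    allowed = set("ACGUNacgun" if is_rna else "ACGTNacgtn")
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    table = _RNA_COMP if is_rna else _DNA_COMP
    return seq.translate(table)[::-1]


def locate_fragment(parent_seq: str, fragment_seq: str) -> list[tuple[int, str]]:
    """All exact occurrences of ``fragment_seq`` or its reverse complement
    in ``parent_seq`` (both U->T normalized), as sorted (0-based offset,
    strand) pairs.  Used to map processed small-RNA fragments (e.g. svRNA4)
    back onto their parent non-coding RNA.
    """
    parent = normalize_seq(parent_seq)
    frag = normalize_seq(fragment_seq)
    if not parent or not frag:
        raise ValueError("parent and fragment must be non-empty")
    hits: list[tuple[int, str]] = []
    for strand, query in (("+", frag), ("-", reverse_complement(frag))):
        start = parent.find(query)
        while start != -1:
            hits.append((start, strand))
            start = parent.find(query, start + 1)
    # A palindromic fragment hits the same offset on both strands; report
    # the forward hit only.
    dedup = {}
    for off, strand in sorted(hits):
        dedup.setdefault(off, (off, strand))
    return sorted(dedup.values())


@dataclass(frozen=True)
class Transcript:
    """A transcript with its genomic placement.

    ``sequence`` is the mature sense-strand sequence (DNA alphabet).  For
    tRNAs with ``has_cca_tail`` it includes the post-transcriptional CCA,
    which the genomic exon blocks do not cover.
    """

    id: str
    sequence: str
    biotype: str
    contig: str
    start: int
    strand: str
    exon_blocks: tuple[tuple[int, int], ...]
    has_cca_tail: bool = False

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_seq(self.sequence))
        object.__setattr__(self, "exon_blocks", tuple(tuple(b) for b in self.exon_blocks))
        self.validate()

    def validate(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.id}: unknown biotype {self.biotype!r}")
        if self.strand not in "+-":
            raise ValueError(f"{self.id}: strand must be + or -")
        if set(self.sequence) - set("ACGTN"):
            raise ValueError(f"{self.id}: sequence contains non-ACGTN characters")
        blocks = self.exon_blocks
        if not blocks:
            raise ValueError(f"{self.id}: no exon blocks")
        for s, e in blocks:
            if not (0 <= s < e):
                raise ValueError(f"{self.id}: bad exon block ({s},{e})")
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            if e1 > s2:
                raise ValueError(f"{self.id}: exon blocks overlap or are unsorted")
        genomic_len = sum(e - s for s, e in blocks)
        expect = len(self.sequence) - (3 if self.has_cca_tail else 0)
        if genomic_len != expect:
            raise ValueError(
                f"{self.id}: exon blocks cover {genomic_len} nt but sequence "
                f"implies {expect}"
            )

    @property
    def genomic_length(self) -> int:
        return sum(e - s for s, e in self.exon_blocks)

    def _sense_blocks(self) -> list[tuple[int, int]]:
        """Exon blocks in transcript (5'->3') order."""
        blocks = list(self.exon_blocks)
        return blocks if self.strand == "+" else blocks[::-1]

    def to_genomic(self, offset: int) -> tuple[str, int, str] | None:
        """Genomic (contig, pos, strand) of a transcript offset, or None for
        CCA-tail positions that have no genomic counterpart."""
        if not (0 <= offset < len(self.sequence)):
            raise IndexError(f"offset {offset} outside {self.id}")
        if offset >= self.genomic_length:  # inside the CCA tail
            return None
        rem = offset
        for s, e in self._sense_blocks():
            blen = e - s
            if rem < blen:
                pos = s + rem if self.strand == "+" else e - 1 - rem
                return (self.contig, pos, self.strand)
            rem -= blen
        raise AssertionError("unreachable")

    def interval_to_genomic(self, start: int, end: int) -> tuple[int, list[tuple[str, int]]]:
        """Map a transcript-space interval [start, end) to genome space.

        Returns ``(genomic_start, cigar)`` where genomic_start is the
        leftmost genomic base and cigar is a list of ('M', n) / ('D', n)
        ops in genomic left-to-right order; D ops are the introns spanned.

        Raises ValueError if the interval reaches into the CCA tail.
        """
        if not (0 <= start < end <= len(self.sequence)):
            raise ValueError(f"bad interval [{start},{end}) for {self.id}")
        if end > self.genomic_length:
            raise ValueError(f"interval reaches into the CCA tail of {self.id}")
        pieces: list[tuple[int, int]] = []  # genomic (s, e) per overlapped exon part
        off = 0
        for s, e in self._sense_blocks():
            blen = e - s
            lo, hi = max(start - off, 0), min(end - off, blen)
            if lo < hi:
                if self.strand == "+":
                    pieces.append((s + lo, s + hi))
                else:
                    pieces.append((e - hi, e - lo))
            off += blen
        pieces.sort()
        gstart = pieces[0][0]
        cigar: list[tuple[str, int]] = []
        prev_end = None
        for s, e in pieces:
            if prev_end is not None and s > prev_end:
                cigar.append(("D", s - prev_end))
            if cigar and cigar[-1][0] == "M" and prev_end == s:
                cigar[-1] = ("M", cigar[-1][1] + e - s)  # abutting blocks merge
            else:
                cigar.append(("M", e - s))
            prev_end = e
        return gstart, cigar

    def splice_from_genome(self, contig_seq: str) -> str:
        """Sense-strand mature sequence implied by the exon blocks (without
        any CCA tail)."""
        spliced = "".join(contig_seq[s:e] for s, e in self.exon_blocks)
        if self.strand == "-":
            spliced = reverse_complement(spliced)
        return spliced


@dataclass(frozen=True)
class CytosineSite:
    """An annotated cytosine in a transcript, e.g. VTRNA1.1 C69."""

    transcript_id: str
    offset: int
    genomic_pos: tuple[str, int, str] | None
    label: str

    @property
    def label_index(self) -> int:
        """1-based cytosine number used in biological labels (C69 = offset 68)."""
        return self.offset + 1


@dataclass(frozen=True)
class JunctionEntry:
    """One splice junction: ``flank_len`` exonic bases either side, in
    transcript sense orientation."""

    junction_id: str
    transcript_id: str
    flank_len: int
    tx_junction_offset: int  # transcript offset of the first base of the right flank
    left_block: tuple[int, int]  # genomic interval of the genomically-left flank
    right_block: tuple[int, int]
    sequence: str

    def __post_init__(self):
        if len(self.sequence) != 2 * self.flank_len:
            raise ValueError(f"{self.junction_id}: sequence length != 2*flank_len")
        # abutting blocks (zero-length intron) are tolerated; hits merge to
        # a single M on back-conversion
        if self.left_block[1] > self.right_block[0]:
            raise ValueError(f"{self.junction_id}: flank blocks overlap")

    @property
    def intron_length(self) -> int:
        return self.right_block[0] - self.left_block[1]


@dataclass
class JunctionLibrary:
    entries: list[JunctionEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def by_id(self, junction_id: str) -> JunctionEntry:
        for e in self.entries:
            if e.junction_id == junction_id:
                return e
        raise KeyError(junction_id)


def build_junction_library(
    transcripts: Iterable[Transcript], flank_len: int = 50
) -> JunctionLibrary:
    """Extract splice junctions from all multi-exon transcripts.

    The per-junction flank is ``min(flank_len, adjacent exon lengths)`` so
    each entry's sequence stays within the two exons that define it.
    """
    lib = JunctionLibrary()
    for tx in transcripts:
        sense = tx._sense_blocks()
        off = 0
        for i, (s, e) in enumerate(sense[:-1]):
            off += e - s
            nxt = sense[i + 1]
            f = min(flank_len, e - s, nxt[1] - nxt[0])
            seq = tx.sequence[off - f : off + f]
            gs_left, _ = tx.interval_to_genomic(off - f, off)
            gs_right, _ = tx.interval_to_genomic(off, off + f)
            left = (gs_left, gs_left + f)
            right = (gs_right, gs_right + f)
            if left[0] > right[0]:  # minus strand: genomic order swaps
                left, right = right, left
            lib.entries.append(
                JunctionEntry(
                    junction_id=f"{tx.id}.j{i + 1}",
                    transcript_id=tx.id,
                    flank_len=f,
                    tx_junction_offset=off,
                    left_block=left,
                    right_block=right,
                    sequence=seq,
                )
            )
    return lib


@dataclass
class ReferenceBundle:
    """Indexed mini-reference: contigs, transcripts, sites, junctions."""

    contigs: dict[str, str]
    transcripts: dict[str, Transcript]
    sites: list[CytosineSite]
    junction_library: JunctionLibrary

    def __post_init__(self):
        self.sites_by_pos = {
            s.genomic_pos: s for s in self.sites if s.genomic_pos is not None
        }
        self.sites_by_tx = {(s.transcript_id, s.offset): s for s in self.sites}
        self.transcripts_by_contig: dict[str, list[Transcript]] = {}
        for tx in self.transcripts.values():
            self.transcripts_by_contig.setdefault(tx.contig, []).append(tx)


def build_reference(
    transcripts: Sequence[Transcript],
    site_annotations: Sequence[tuple[str, int, str]],
    contigs: dict[str, str],
    flank_len: int = 50,
) -> ReferenceBundle:
    """Validate and index a mini-reference.

    Parameters
    ----------
    transcripts
        Validated :class:`Transcript` objects.
    site_annotations
        ``(transcript_id, offset, label)`` triples; the reference base at
        each offset must be C.
    contigs
        Genome view: contig name -> sequence.  Each transcript's spliced
        genomic sequence must reproduce its stored sequence (minus CCA).
    flank_len
        Junction flank length in nt; default 50, the seed-length scale of
        the reads being rescued.
    """
    tx_index: dict[str, Transcript] = {}
    for tx in transcripts:
        if tx.id in tx_index:
            raise ValueError(f"duplicate transcript id {tx.id!r}")
        if tx.contig not in contigs:
            raise ValueError(f"{tx.id}: contig {tx.contig!r} not in genome")
        spliced = tx.splice_from_genome(contigs[tx.contig])
        body = tx.sequence[: tx.genomic_length]
        if spliced != body:
            raise ValueError(f"{tx.id}: sequence does not match genome at exon blocks")
        tx_index[tx.id] = tx

    sites: list[CytosineSite] = []
    for tx_id, offset, label in site_annotations:
        if tx_id not in tx_index:
            raise ValueError(f"site {label!r}: unknown transcript {tx_id!r}")
        tx = tx_index[tx_id]
        if tx.sequence[offset] != "C":
            raise ValueError(
                f"site {label!r}: reference base at {tx_id}:{offset} is "
                f"{tx.sequence[offset]!r}, not C"
            )
        sites.append(
            CytosineSite(
                transcript_id=tx_id,
                offset=offset,
                genomic_pos=tx.to_genomic(offset),
                label=label,
            )
        )

    lib = build_junction_library(tx_index.values(), flank_len=flank_len)
    return ReferenceBundle(
        contigs=dict(contigs),
        transcripts=tx_index,
        sites=sites,
        junction_library=lib,
    )


# ---------------------------------------------------------------------------
# File interfaces


def write_genome_fasta(bundle: ReferenceBundle, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in bundle.contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_transcript_fasta(bundle: ReferenceBundle, path) -> None:
    records = [
        SeqRecord(Seq(tx.sequence), id=tx.id, description=tx.biotype)
        for tx in bundle.transcripts.values()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_exon_bed(bundle: ReferenceBundle, path) -> None:
    """BED6, one row per exon block."""
    with open(path, "w") as fh:
        for tx in bundle.transcripts.values():
            for i, (s, e) in enumerate(tx.exon_blocks):
                fh.write(f"{tx.contig}\t{s}\t{e}\t{tx.id}.exon{i + 1}\t0\t{tx.strand}\n")


def write_site_table(bundle: ReferenceBundle, path) -> None:
    """TSV site table: contig, pos0, strand, label, transcript_id."""
    with open(path, "w") as fh:
        fh.write("contig\tpos0\tstrand\tlabel\ttranscript_id\n")
        for s in bundle.sites:
            if s.genomic_pos is None:
                continue
            c, p, st = s.genomic_pos
            fh.write(f"{c}\t{p}\t{st}\t{s.label}\t{s.transcript_id}\n")
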