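"""3' adapter trimming and minimum-length filtering for small-RNA reads.

Implements the classic small-RNA trimming contract: find the longest read
suffix that aligns to a prefix of the adapter with at least ``stringency``
overlap and a mismatch fraction of at most ``error_rate``, remove it, and
drop reads shorter than ``min_length`` afterwards.  Single-end 3'-only;
no quality trimming (constant-quality small-RNA libraries).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .simulate import DEFAULT_ADAPTER


@dataclass
class TrimParams:
    adapter: str = DEFAULT_ADAPTER
    stringency: int = 3       # minimum read-suffix / adapter-prefix overlap, nt
    error_rate: float = 0.2   # max mismatch fraction within the overlap
    min_length: int = 20      # reads shorter than this after trimming are dropped

    def __post_init__(self):
        if self.stringency < 1:
            raise ValueError("stringency must be >= 1")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        self.adapter = self.adapter.upper()


def trim_read(read: str, params: TrimParams) -> str | None:
    """Trim the 3' adapter from one read.

    Returns the trimmed read, or ``None`` when the trimmed read falls
    below ``min_length`` (dropped).  Among candidate trim positions of
    equal suffix length, the earlier (more-trimmed) one wins.
    """
    if not read:
        raise ValueError("empty read")
    read = read.upper()
    n = len(read)
    alen = len(params.adapter)
    cut = n  # default: no adapter found, keep everything
    for i in range(n):  # earliest (longest-suffix) candidate wins
        overlap = min(n - i, alen)
        if overlap < params.stringency:
            break
        max_mm = int(params.error_rate * overlap)
        mm = 0
        for a, b in zip(read[i : i + overlap], params.adapter[:overlap]):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        if mm <= max_mm:
            cut = i
            break
    trimmed = read[:cut]
    if len(trimmed) < params.min_length:
        return None
    return trimmed


@dataclass
class TrimStats:
    n_in: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    n_trimmed: int = 0  # kept reads that lost at least one base

    def check(self) -> None:
        assert self.n_in == self.n_kept + self.n_dropped


def trim_fastq(path_in, params: TrimParams, path_out=None) -> tuple[Path, TrimStats]:
    """Trim a FASTQ file; returns the output path and counts."""
    path_in = Path(path_in)
    if path_out is None:
        path_out = path_in.with_suffix(".trimmed.fastq")
    path_out = Path(path_out)
    stats = TrimStats()
    with open(path_out, "w") as out:
        for rec in SeqIO.parse(str(path_in), "fastq"):
            stats.n_in += 1
            seq = str(rec.seq)
            trimmed = trim_read(seq, params)
            if trimmed is None:
                stats.n_dropped += 1
                continue
            stats.n_kept += 1
            if len(trimmed) < len(seq):
                stats.n_trimmed += 1
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"][: len(trimmed)]
            )
            out.write(f"@{rec.id}\n{trimmed}\n+\n{qual}\n")
    stats.check()
    return path_out, stats
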