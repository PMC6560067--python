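"""Per-read methylation calling, artifact filtering, per-site pileup.

A bisulfite read reports each covered reference cytosine as methylated
(read C), unmethylated (read T, i.e. converted), or uninformative (any
other base, or a position spanned by a cigar D gap).  Reads in which more
than a third of the informative cytosines read as methylated are
discarded as non-conversion artifacts from highly structured regions —
in such reads conversion fails wholesale, mimicking dense methylation.
All cytosines are reported regardless of sequence context (RNA m5C has
no CpG special-casing).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .align import AlignmentRecord
from .reference import ReferenceBundle

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
UNINFORMATIVE = "uninformative"


@dataclass
class ArtifactFilterParams:
    max_meth_fraction: float = 1.0 / 3.0  # discard when strictly above
    min_informative_c: int = 1            # filter applies only with >= this many calls

    def __post_init__(self):
        if not (0.0 < self.max_meth_fraction <= 1.0):
            raise ValueError("max_meth_fraction must be in (0, 1]")
        if self.min_informative_c < 0:
            raise ValueError("min_informative_c must be >= 0")


@dataclass
class ReadMethylationCall:
    read_id: str
    calls: list[tuple[tuple[str, int, str], str]]  # ((contig, pos, strand), state)
    n_meth: int
    n_unmeth: int

    @property
    def n_informative(self) -> int:
        return self.n_meth + self.n_unmeth


def call_read(record: AlignmentRecord, bundle: ReferenceBundle) -> ReadMethylationCall:
    """Call the methylation state of every reference C covered by an M op.

    Positions inside D gaps never produce calls; read bases other than
    C/T over a reference C are uninformative (sequencing error or SNV).
    """
    read = record.seq
    calls: list[tuple[tuple[str, int, str], str]] = []
    n_meth = n_unmeth = 0
    for read_pos, contig, gpos, ref_base in record.aligned_pairs(bundle):
        if ref_base != "C":
            continue
        base = read[read_pos]
        if base == "C":
            state = METHYLATED
            n_meth += 1
        elif base == "T":
            state = UNMETHYLATED
            n_unmeth += 1
        else:
            state = UNINFORMATIVE
        calls.append(((contig, gpos, record.strand), state))
    return ReadMethylationCall(record.read_id, calls, n_meth, n_unmeth)


def filter_artifact_reads(
    calls: list[ReadMethylationCall], params: ArtifactFilterParams | None = None
) -> tuple[list[ReadMethylationCall], list[ReadMethylationCall]]:
    """Partition reads by the strict >1/3-methylated-cytosines rule.

    A read is discarded when ``n_meth / (n_meth + n_unmeth) >
    max_meth_fraction`` and it has at least ``min_informative_c``
    informative calls; reads with no informative cytosines are kept
    (no evidence of an artifact).
    """
    params = params or ArtifactFilterParams()
    kept, discarded = [], []
    for call in calls:
        n = call.n_informative
        if n >= params.min_informative_c and n > 0 and (
            call.n_meth / n > params.max_meth_fraction
        ):
            discarded.append(call)
        else:
            kept.append(call)
    return kept, discarded


def pileup(
    kept_calls: list[ReadMethylationCall],
    bundle: ReferenceBundle | None = None,
    condition: str = "",
    replicate: int = 0,
) -> pd.DataFrame:
    """Aggregate one replicate's read calls into per-site counts.

    Returns a table with one row per covered cytosine: contig, pos,
    strand, n_meth, n_unmeth, coverage, level (= n_meth / coverage), plus
    the site label and transcript when the position is annotated.  Sites
    with zero informative coverage are omitted.
    """
    acc: dict[tuple[str, int, str], list[int]] = {}
    for call in kept_calls:
        for pos, state in call.calls:
            if state == UNINFORMATIVE:
                continue
            c = acc.setdefault(pos, [0, 0])
            if state == METHYLATED:
                c[0] += 1
            else:
                c[1] += 1
    rows = []
    for (contig, gpos, strand), (n_meth, n_unmeth) in sorted(acc.items()):
        cov = n_meth + n_unmeth
        site = bundle.sites_by_pos.get((contig, gpos, strand)) if bundle else None
        rows.append(
            {
                "contig": contig,
                "pos": gpos,
                "strand": strand,
                "label": site.label if site else "",
                "transcript": site.transcript_id if site else "",
                "condition": condition,
                "replicate": replicate,
                "n_meth": n_meth,
                "n_unmeth": n_unmeth,
                "coverage": cov,
                "level": n_meth / cov,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "pos", "strand", "label", "transcript", "condition",
            "replicate", "n_meth", "n_unmeth", "coverage", "level",
        ],
    )


def write_site_outputs(table: pd.DataFrame, prefix) -> tuple[Path, Path]:
    """Write a bedGraph (percent methylation) and a counts TSV.

    The bedGraph value is the level as a percentage (0.5 -> 50.0); the
    counts TSV carries every column so ``read_site_counts`` round-trips
    the table exactly.
    """
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bedGraph")
    counts_path = prefix.with_suffix(".counts.tsv")
    with open(bed_path, "w") as fh:
        fh.write("#contig\tstart\tend\tmethylation_percent\n")
        for _, row in table.iterrows():
            fh.write(
                f"{row.contig}\t{row.pos}\t{row.pos + 1}\t{100.0 * row.level:.6g}\n"
            )
    table.to_csv(counts_path, sep="\t", index=False)
    return bed_path, counts_path


def read_site_counts(counts_path) -> pd.DataFrame:
    df = pd.read_csv(
        counts_path,
        sep="\t",
        dtype={"contig": str, "label": str, "transcript": str, "condition": str},
        keep_default_na=False,
    )
    df["level"] = df["n_meth"] / df["coverage"]
    return df
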