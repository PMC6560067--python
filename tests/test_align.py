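"""Three-pass bisulfite alignment: scoring, CCA rescue, junction rescue."""

import numpy as np
import pytest

from rnam5c.align import (
    AlignParams,
    align_pass1,
    align_reads,
    bs_match_score,
    clip_and_realign,
    convert_to_genomic,
    junction_align,
    read_sam,
    write_sam,
    AlignmentRecord,
)
from rnam5c.reference import Transcript, build_reference

from conftest import make_single_site_reference
from oracles import brute_force_align


def _convert(seq: str) -> str:
    """Fully bisulfite-convert an unmethylated sequence (every C -> T)."""
    return seq.replace("C", "T")


class TestBsMatchScore:
    @pytest.mark.parametrize(
        "read,ref,expected",
        [
            ("ATGT", "ACGT", 0),  # C->T conversion is not a mismatch
            ("ACGT", "ACGT", 0),  # retained C = methylated
            ("ACGT", "ATGT", 1),  # read C over ref T IS a mismatch
            ("ANGT", "ACGT", 1),  # N matches nothing
            ("TTTT", "CCCC", 0),
            ("CCCC", "TTTT", 4),
        ],
    )
    def test_asymmetry(self, read, ref, expected):
        assert bs_match_score(read, ref) == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bs_match_score("ACG", "ACGT")


class TestPass1:
    def test_converted_read_maps_to_origin(self):
        ref = make_single_site_reference(seed=6, tx_len=60, site_offset=30)
        tx = ref.transcripts["SITE1"]
        reads = []
        for start in (0, 10, 25):
            reads.append((f"r{start}", _convert(tx.sequence[start : start + 30])))
        outcomes = align_pass1(reads, ref, AlignParams())
        for (rid, _), out in zip(reads, outcomes):
            start = int(rid[1:])
            assert out.outcome_class == "unique"
            assert out.record.contig == "chrS"
            assert out.record.start == tx.start + start
            assert out.record.strand == "+"
            assert out.record.bs_mismatches == 0

    def test_duplicated_region_is_ambiguous(self):
        block = "ACGGATTACAGGATCCAGTTACGGATCCAA"
        rng = np.random.default_rng(0)
        filler = rng.choice(list("ACGT"), size=40)
        contig = block + "".join(filler) + block
        tx = Transcript("t", contig, "other", "c", 0, "+", ((0, len(contig)),))
        bundle = build_reference([tx], [], {"c": contig})
        [out] = align_pass1([("r", _convert(block))], bundle, AlignParams())
        assert out.outcome_class == "ambiguous"

    def test_random_read_unaligned(self):
        ref = make_single_site_reference(seed=6)
        read = "ATATATATATATATATATATGCGCGCGCGC"
        expect_cls, _, _ = brute_force_align(read, ref.contigs, 2)
        [out] = align_pass1([("r", read)], ref, AlignParams())
        assert out.outcome_class == expect_cls == "unaligned"

    def test_minus_strand_hit(self):
        ref = make_single_site_reference(seed=6, tx_len=60, site_offset=30)
        tx = ref.transcripts["SITE1"]
        # a read that is the reverse complement of a transcript window maps
        # to the minus strand of the contig (in C->T space of its own sense)
        from rnam5c.reference import reverse_complement

        sense = reverse_complement(ref.contigs["chrS"][50:80])
        [out] = align_pass1([("r", _convert(sense))], ref, AlignParams())
        assert out.outcome_class == "unique"
        assert (out.record.strand, out.record.start) == ("-", 50)

    def test_empty_reference_rejected(self):
        ref = make_single_site_reference()
        ref.contigs = {}
        with pytest.raises(ValueError):
            align_pass1([("r", "ACGT")], ref, AlignParams())


class TestOracleEquivalence:
    def test_pass1_equals_brute_force(self, demo_ref):
        """Exhaustive-scan aligner agrees with an independent double-loop
        brute-force implementation on random reads: same outcome class,
        locus, and mismatch count."""
        rng = np.random.default_rng(12)
        reads = []
        txs = list(demo_ref.transcripts.values())
        for i in range(60):
            kind = i % 3
            if kind == 0:  # clean converted read
                tx = txs[i % len(txs)]
                s = int(rng.integers(0, len(tx.sequence) - 30))
                seq = _convert(tx.sequence[s : s + 30])
            elif kind == 1:  # mutated read
                tx = txs[i % len(txs)]
                s = int(rng.integers(0, len(tx.sequence) - 30))
                seq = list(_convert(tx.sequence[s : s + 30]))
                for p in rng.integers(0, 30, size=int(rng.integers(1, 4))):
                    seq[p] = "ACGT"[int(rng.integers(4))]
                seq = "".join(seq)
            else:  # random read
                seq = "".join(rng.choice(list("ACGT"), size=30))
            reads.append((f"r{i}", seq))
        outcomes = align_pass1(reads, demo_ref, AlignParams())
        for (rid, seq), out in zip(reads, outcomes):
            cls, locus, mm = brute_force_align(seq, demo_ref.contigs, 2)
            assert out.outcome_class == cls, rid
            if cls == "unique":
                rec = out.record
                assert (rec.contig, rec.start, rec.strand) == locus, rid
                assert rec.bs_mismatches == mm, rid


class TestCCARescue:
    def test_tail_read_rescued_at_pass2(self, demo_ref):
        """A converted tRNA 3'-end read bearing the genome-absent CCA tail
        fails pass 1 (3 terminal mismatches) and maps uniquely after the
        3-base clip."""
        tx = demo_ref.transcripts["tRNA-Demo"]
        read = _convert(tx.sequence[-30:])  # last 27 genomic nt + converted CCA
        [p1] = align_pass1([("tail", read)], demo_ref, AlignParams())
        assert p1.outcome_class == "unaligned"
        [p2] = clip_and_realign([("tail", read)], demo_ref, AlignParams())
        assert p2.outcome_class == "unique"
        rec = p2.record
        assert rec.pass_label == 2
        assert rec.clipped_tail == 3
        assert rec.contig == tx.contig
        assert rec.start == tx.exon_blocks[0][1] - 27  # true 3'-end locus

    def test_short_read_discarded_after_clip(self, demo_ref):
        read = "A" * 21  # 21 - 3 = 18 < 20
        [out] = clip_and_realign([("short", read)], demo_ref, AlignParams())
        assert out.outcome_class == "discarded_short"

    def test_still_ambiguous_after_clip(self):
        block = "ACGGATTACAGGATCCAGTTACGGATCCAATTG"
        rng = np.random.default_rng(1)
        contig = block + "".join(rng.choice(list("ACGT"), size=40)) + block
        tx = Transcript("t", contig, "other", "c", 0, "+", ((0, len(contig)),))
        bundle = build_reference([tx], [], {"c": contig})
        read = _convert(block[:30])
        [out] = clip_and_realign([("r", read)], bundle, AlignParams())
        assert out.outcome_class == "ambiguous"


class TestJunctionRescue:
    def test_centred_junction_read(self, demo_ref):
        """A read centred on the splice junction converts back to genomic
        coordinates with the intron as a cigar D op."""
        tx = demo_ref.transcripts["SPLICED-Demo"]
        entry = demo_ref.junction_library.entries[0]
        j = entry.tx_junction_offset
        read = _convert(tx.sequence[j - 10 : j + 10])
        [out] = junction_align([("jr", read)], demo_ref, AlignParams())
        assert out.outcome_class == "unique"
        rec = out.record
        assert rec.contig == tx.contig
        assert rec.pass_label == 3
        assert rec.cigar == (("M", 10), ("D", entry.intron_length), ("M", 10))
        assert rec.start == entry.left_block[1] - 10

    def test_asymmetric_split(self, demo_ref):
        tx = demo_ref.transcripts["SPLICED-Demo"]
        entry = demo_ref.junction_library.entries[0]
        j = entry.tx_junction_offset
        read = _convert(tx.sequence[j - 19 : j + 1])  # 19 nt left / 1 nt right
        [out] = junction_align([("jr", read)], demo_ref, AlignParams())
        assert out.outcome_class == "unique"
        assert out.record.cigar == (
            ("M", 19), ("D", entry.intron_length), ("M", 1)
        )

    def test_heavily_errored_junction_read_unaligned(self, demo_ref):
        tx = demo_ref.transcripts["SPLICED-Demo"]
        j = demo_ref.junction_library.entries[0].tx_junction_offset
        read = list(_convert(tx.sequence[j - 10 : j + 10]))
        read[0], read[5], read[12] = "N", "N", "N"  # 3 errors > 2 allowed
        [out] = junction_align([("jr", "".join(read))], demo_ref, AlignParams())
        assert out.outcome_class == "unaligned"

    def test_zero_gap_junction_merges_to_single_m(self):
        # abutting exon blocks: degenerate "junction" with no intron
        genome = "ACGTACGTAAGGTTCCGGTTCCAAGGTTAA"
        seq = genome[:10] + genome[10:20]
        tx = Transcript("t", seq, "mRNA", "c", 0, "+",
                        ((0, 10), (10, 20)))
        bundle = build_reference([tx], [], {"c": genome}, flank_len=5)
        rec = AlignmentRecord(
            read_id="r", contig="t.j1", start=2, strand="+",
            cigar=(("M", 6),), bs_mismatches=0, pass_label=3,
            clipped_tail=0, seq=_convert(seq[7:13]),
        )
        gen = convert_to_genomic(rec, bundle)
        assert gen.cigar == (("M", 6),)
        assert gen.start == 7

    def test_outside_flank_rejected(self, demo_ref):
        entry = demo_ref.junction_library.entries[0]
        rec = AlignmentRecord(
            read_id="r", contig=entry.junction_id, start=95, strand="+",
            cigar=(("M", 10),), bs_mismatches=0, pass_label=3,
            clipped_tail=0, seq="A" * 10,
        )
        with pytest.raises(ValueError, match="outside junction flanks"):
            convert_to_genomic(rec, demo_ref)


class TestCascade:
    def test_conservation_and_monotonicity(self, demo_ref):
        rng = np.random.default_rng(5)
        txs = list(demo_ref.transcripts.values())
        reads = []
        for i in range(120):
            tx = txs[i % len(txs)]
            s = int(rng.integers(0, len(tx.sequence) - 23))
            seq = _convert(tx.sequence[s : s + min(30, len(tx.sequence) - s)])
            if i % 4 == 0:  # sprinkle errors
                seq = list(seq)
                for p in rng.integers(0, len(seq), size=int(rng.integers(0, 4))):
                    seq[p] = "ACGT"[int(rng.integers(4))]
                seq = "".join(seq)
            reads.append((f"r{i}", seq))
        outcomes, stats = align_reads(reads, demo_ref, AlignParams())
        assert len(outcomes) == len(reads)  # exactly one outcome per read
        classes = [o.outcome_class for o in outcomes]
        assert set(classes) <= {"unique", "ambiguous", "unaligned", "discarded_short"}
        # pass-level conservation
        p1 = stats.per_pass["pass1"]
        p2 = stats.per_pass["pass2"]
        p3 = stats.per_pass["pass3"]
        assert sum(p1.values()) == len(reads)
        assert sum(p2.values()) == sum(
            v for k, v in p1.items() if k in ("ambiguous", "unaligned")
        )
        assert sum(p3.values()) == p2.get("unaligned", 0)
        # monotonicity: a stricter mismatch ceiling never rescues a read
        strict, _ = align_reads(reads, demo_ref, AlignParams(max_mismatch=0))
        for lax, hard in zip(outcomes, strict):
            if lax.outcome_class == "unaligned":
                assert hard.outcome_class in ("unaligned", "discarded_short")

    def test_simulator_reads_map_to_true_origin(self):
        """Error-free converted simulator reads map uniquely to their true
        source offset (full-length inserts only)."""
        from rnam5c.simulate import MethylationProfile, SimulationConfig, simulate_replicate

        ref = make_single_site_reference(seed=10, tx_len=80, site_offset=40)
        cfg = SimulationConfig(
            conversion_efficiency=1.0, artifact_rate=0.0, mean_coverage=40, seed=1
        )
        reads, truth = simulate_replicate(ref, MethylationProfile(), cfg, "x", 1)
        tx = ref.transcripts["SITE1"]
        full = [
            (r.read_id, r.sequence)
            for r, row in zip(reads, truth.itertuples(index=False))
            if row.insert_len == cfg.read_length
        ]
        starts = {row.read_id: row.start for row in truth.itertuples(index=False)}
        outcomes = align_pass1(full, ref, AlignParams())
        n_unique = 0
        for out in outcomes:
            if out.outcome_class == "unique":
                n_unique += 1
                assert out.record.start == tx.start + starts[out.read_id]
        assert n_unique / len(full) > 0.95


class TestSamRoundTrip:
    def test_write_read_identity(self, demo_ref, tmp_path):
        tx = demo_ref.transcripts["SPLICED-Demo"]
        entry = demo_ref.junction_library.entries[0]
        j = entry.tx_junction_offset
        reads = [
            ("a", _convert(tx.sequence[5:35])),
            ("b", _convert(tx.sequence[j - 10 : j + 10])),
        ]
        outcomes, _ = align_reads(reads, demo_ref, AlignParams())
        sam = tmp_path / "roundtrip.sam"
        write_sam(outcomes, demo_ref, sam)
        records = read_sam(sam, demo_ref)
        by_id = {r.read_id: r for r in records}
        for out in outcomes:
            if out.outcome_class != "unique":
                continue
            rec, rt = out.record, by_id[out.read_id]
            assert (rec.contig, rec.start, rec.strand) == (rt.contig, rt.start, rt.strand)
            assert rec.cigar == rt.cigar
            assert rec.seq == rt.seq
            assert (rec.pass_label, rec.clipped_tail, rec.bs_mismatches) == (
                rt.pass_label, rt.clipped_tail, rt.bs_mismatches
            )
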