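"""VCF round trips, QC filtering, pooling and protein annotation."""

import numpy as np
import pytest
from Bio.Seq import Seq

from canisom import variant_io
from canisom.simulate import CohortConfig, generate_cohort
from canisom.variant_io import (
    Transcript,
    TranscriptModel,
    TranscriptModelError,
    VariantCall,
    annotate,
    pool_unique,
    qc_filter,
    read_vcf,
    write_vcf,
)

from conftest import make_call


class TestVariantCall:
    def test_vaf_is_alt_over_depth(self):
        assert make_call(depth=100, alt_depth=40).vaf == pytest.approx(0.40)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(pos=0),
            dict(ref="A", alt="A"),
            dict(depth=10, alt_depth=11),
        ],
    )
    def test_invariants_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_call(**kwargs)


class TestVcfRoundTrip:
    def test_round_trip_identity(self, tmp_path, small_cohort):
        sample = small_cohort.metadata["sample_id"].iloc[0]
        calls = [c for c in small_cohort.calls if c.sample_id == sample]
        path = tmp_path / "s.vcf"
        write_vcf(path, calls)
        back = read_vcf(path)
        orig = {
            (c.key, c.depth, c.alt_depth, round(c.fs, 3), round(c.qd, 2))
            for c in calls
        }
        got = {
            (c.key, c.depth, c.alt_depth, round(c.fs, 3), round(c.qd, 2))
            for c in back
        }
        assert got == orig

    def test_multiallelic_split(self, tmp_path):
        path = tmp_path / "m.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1>\n"
            '##INFO=<ID=FS,Number=1,Type=Float,Description="fs">\n'
            '##INFO=<ID=QD,Number=1,Type=Float,Description="qd">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t100\t.\tA\tC,T\t.\t.\tFS=1.0;QD=20.0\tGT:DP:AD\t0/1:100:40,35,25\n"
        )
        calls = read_vcf(path)
        assert [(c.alt, c.alt_depth) for c in calls] == [("C", 35), ("T", 25)]
        assert all(c.depth == 100 for c in calls)

    def test_corrupt_vcf_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text("this is not a vcf\n")
        with pytest.raises(variant_io.VcfFormatError):
            read_vcf(path)


class TestQcFilter:
    def test_boundaries_pass_and_low_depth_rejected(self):
        boundary = make_call(fs=30.0, qd=2.0, depth=10, alt_depth=5)
        shallow = make_call(depth=9, alt_depth=4)
        high_fs = make_call(fs=30.01)
        low_qd = make_call(qd=1.99)
        passing, rejected = qc_filter([boundary, shallow, high_fs, low_qd])
        assert passing == [boundary]
        assert rejected == [shallow, high_fs, low_qd]

    def test_missing_annotations_pass(self):
        call = make_call(fs=None, qd=None)
        passing, rejected = qc_filter([call])
        assert passing == [call] and rejected == []

    def test_idempotent_and_order_preserved(self, small_cohort):
        passing, rejected = qc_filter(small_cohort.calls)
        again, none = qc_filter(passing)
        assert again == passing and none == []
        assert passing + rejected != [] and set(map(id, passing + rejected)) == set(
            map(id, small_cohort.calls)
        )

    def test_fail_rate_recovered(self):
        cohort = generate_cohort(
            CohortConfig(n_samples=30, qc_fail_rate=0.2, seed=3)
        )
        _, rejected = qc_filter(cohort.calls)
        frac = len(rejected) / len(cohort.calls)
        # binomial 3-sigma band around the configured rate
        sigma = (0.2 * 0.8 / len(cohort.calls)) ** 0.5
        assert abs(frac - 0.2) < 3 * sigma + 0.005


class TestPoolUnique:
    def test_shared_and_private_counting(self):
        calls = [
            make_call(sample=s, pos=100) for s in ("S1", "S2", "S3")
        ] + [
            make_call(sample="S1", pos=200),
            make_call(sample="S2", pos=300),
        ]
        pooled = pool_unique(calls)
        assert len(pooled) == 3  # unique
        assert sum(m.n_carriers for m in pooled) == 5  # total

    def test_empty_input(self):
        assert pool_unique([]) == []

    def test_duplicate_sample_key_keeps_max_depth(self, caplog):
        dup = [
            make_call(depth=50, alt_depth=25),
            make_call(depth=200, alt_depth=100),
        ]
        with caplog.at_level("WARNING"):
            pooled = pool_unique(dup)
        assert len(pooled) == 1 and pooled[0].n_carriers == 1
        assert pooled[0].vafs[0] == pytest.approx(0.5)
        assert "duplicate" in caplog.text

    def test_total_matches_generator_emissions(self, small_cohort):
        pooled = pool_unique(small_cohort.calls)
        assert sum(m.n_carriers for m in pooled) == len(small_cohort.calls)
        assert len(pooled) == len(
            small_cohort.truth.groupby(["chrom", "pos", "ref", "alt"])
        )

    def test_filtering_commutes_with_pooling(self, small_cohort):
        passing, _ = qc_filter(small_cohort.calls)
        direct = {m.key: set(m.carriers) for m in pool_unique(passing)}
        assert direct  # non-trivial
        # pooling first, then restricting carriers to QC-passing calls
        keep = {(c.sample_id, c.key) for c in passing}
        indirect = {}
        for m in pool_unique(small_cohort.calls):
            carriers = {s for s in m.carriers if (s, m.key) in keep}
            if carriers:
                indirect[m.key] = carriers
        assert direct == indirect


class TestAnnotate:
    def test_v588e_on_plus_strand(self, toy_transcript_plus):
        # codon 588 occupies CDS offsets 1761..1763 -> genomic 2762..2764
        call = make_call(pos=1001 + 1762, ref="T", alt="A")
        annotate([call], toy_transcript_plus)
        assert (call.gene, call.codon, call.protein_change) == ("BRAF", 588, "V588E")
        assert call.mutation_class == "substitution"

    def test_reverse_strand_matches_translation_oracle(self, toy_transcript_minus):
        tx = toy_transcript_minus["BRAF"]
        genome = str(Seq(tx.cds_seq).reverse_complement())
        rng = np.random.default_rng(5)
        checked = 0
        for _ in range(40):
            gpos = int(rng.integers(tx.exons[0][0], tx.exons[0][1] + 1))
            idx = gpos - tx.exons[0][0]
            ref = genome[idx]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            call = make_call(pos=gpos, ref=ref, alt=str(alt))
            annotate([call], toy_transcript_minus)
            # oracle: mutate the genome, re-translate the whole CDS
            mutated = genome[:idx] + str(alt) + genome[idx + 1 :]
            prot_ref = str(Seq(genome).reverse_complement().translate())
            prot_alt = str(Seq(mutated).reverse_complement().translate())
            diffs = [i for i, (a, b) in enumerate(zip(prot_ref, prot_alt)) if a != b]
            if not diffs:  # synonymous
                aa = prot_ref[call.codon - 1]
                assert call.protein_change == f"{aa}{call.codon}{aa}"
            else:
                (i,) = diffs
                expected = f"{prot_ref[i]}{i + 1}{prot_alt[i]}"
                assert call.protein_change == expected
            checked += 1
        assert checked == 40

    def test_intergenic_call_retained_unannotated(self, toy_transcript_plus):
        call = make_call(chrom="chr9", pos=5)
        (out,) = annotate([call], toy_transcript_plus)
        assert out.gene is None and out.protein_change is None

    def test_in_frame_deletion_classified(self, toy_transcript_plus):
        tx = toy_transcript_plus["BRAF"]
        start = tx.exons[0][0]
        genome = tx.cds_seq  # plus strand
        pos = start + 29  # anchor inside CDS
        ref = genome[29:33]
        call = make_call(pos=pos, ref=ref, alt=ref[0])
        annotate([call], toy_transcript_plus)
        assert call.mutation_class == "in_frame_indel"
        assert call.gene == "BRAF" and call.protein_change.endswith("del")

    def test_frameshift_classified(self, toy_transcript_plus):
        tx = toy_transcript_plus["BRAF"]
        start = tx.exons[0][0]
        ref = tx.cds_seq[10:12]
        call = make_call(pos=start + 10, ref=ref, alt=ref[0])
        annotate([call], toy_transcript_plus)
        assert call.mutation_class == "frameshift"

    def test_stop_gain_is_truncation(self):
        # construct a codon TAC (Tyr); mutate C->G at third base -> TAG stop
        seq = "ATG" + "TAC" + "GGG"
        tx = TranscriptModel([Transcript("G1", "chr1", "+", ((11, 19),), seq)])
        call = make_call(pos=16, ref="C", alt="G")
        annotate([call], tx)
        assert call.protein_change == "Y2*"
        assert call.mutation_class == "truncation"


class TestTranscriptModel:
    def test_overlapping_transcripts_rejected(self):
        t1 = Transcript("A", "chr1", "+", ((100, 105),), "ATGTAA")
        t2 = Transcript("B", "chr1", "+", ((104, 109),), "ATGTGA")
        with pytest.raises(TranscriptModelError):
            TranscriptModel([t1, t2])

    def test_offset_roundtrip_both_strands(self):
        for strand in "+-":
            tx = Transcript("G", "chr1", strand, ((101, 106), (201, 206)), "ATGAAACCCTGA")
            for off in range(12):
                assert tx.cds_offset(tx.genomic_pos(off)) == off
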