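"""Size/type classification, VCF and SyRI ingestion, normalization."""

import io
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omniindel import variants as var
from omniindel.variants import (
    GenotypeCall,
    IndelRecord,
    SizeClass,
    Source,
    VariantType,
    classify_size,
    classify_type,
    normalize_indel,
    parse_syri_indels,
    read_vcf_indels,
    site_stats,
)


@pytest.mark.parametrize(
    "length,expected",
    [
        (1, SizeClass.SOI),
        (2, SizeClass.SOI),
        (3, SizeClass.MOI),
        (49, SizeClass.MOI),
        (50, SizeClass.LOI),
        (999, SizeClass.LOI),
        (1000, SizeClass.HOI),
        (1500, SizeClass.HOI),
        (9_400_000, SizeClass.HOI),
    ],
)
def test_size_class_boundaries(length, expected):
    assert classify_size(length) is expected


def test_size_class_rejects_zero():
    with pytest.raises(ValueError):
        classify_size(0)


@given(st.integers(min_value=1, max_value=10_000_000))
def test_size_class_partition_is_total_and_monotone(n):
    cls = classify_size(n)
    assert cls in SizeClass
    order = [SizeClass.SOI, SizeClass.MOI, SizeClass.LOI, SizeClass.HOI]
    if n > 1:
        assert order.index(classify_size(n - 1)) <= order.index(cls)


@pytest.mark.parametrize(
    "changes,expected",
    [
        ((4,), VariantType.INS),
        ((-7, -2), VariantType.DEL),
        ((-2, 1), VariantType.MIXED),
        ((5, -5), VariantType.MIXED),
    ],
)
def test_type_classification(changes, expected):
    assert var.classify_type_from_changes(changes) is expected


def test_type_rejects_all_zero():
    with pytest.raises(ValueError):
        var.classify_type_from_changes((0, 0))


def _write_vcf_text(tmp_path, body):
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=1000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4\n"
    )
    path = tmp_path / "in.vcf"
    path.write_text(header + body)
    return path


def test_read_vcf_keeps_indels_drops_snps(tmp_path):
    body = (
        "chr1\t10\t.\tA\tAT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t./.\n"
        "chr1\t20\t.\tC\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/0\n"
        "chr1\t30\t.\tACG\tA,ACGT\t.\tPASS\t.\tGT\t0/1\t0/2\t1/2\t0/0\n"
    )
    out = read_vcf_indels(_write_vcf_text(tmp_path, body))
    assert len(out) == 2
    ins, mixed = out[0][0], out[1][0]
    assert ins.length_changes == (1,)
    assert ins.variant_type is VariantType.INS
    assert mixed.length_changes == (-2, 1)
    assert mixed.variant_type is VariantType.MIXED
    assert mixed.size_class is SizeClass.SOI


def test_read_vcf_missing_gt_warns_and_retains(tmp_path):
    body = "chr1\t10\t.\tA\tATTT\t.\tPASS\t.\tDP\t5\t5\t5\t5\n"
    with pytest.warns(UserWarning, match="GT"):
        out = read_vcf_indels(_write_vcf_text(tmp_path, body))
    assert len(out) == 1
    assert all(c.is_missing for c in out[0][1])


def test_read_vcf_malformed_line_reports_position(tmp_path):
    body = "chr1\tnot_a_number\t.\tA\tAT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/0\n"
    with pytest.raises(Exception):
        read_vcf_indels(_write_vcf_text(tmp_path, body))


def test_site_stats_hand_counted():
    rec = IndelRecord.from_alleles("chr1", 9, "A", ["AT"])
    calls = [
        GenotypeCall("a", (0, 0)),
        GenotypeCall("b", (0, 1)),
        GenotypeCall("c", (1, 1)),
        GenotypeCall("d", (None, None)),
    ]
    st_ = site_stats(rec, calls)
    assert st_.maf == pytest.approx(0.5)  # 3 ref / 3 alt of 6 observed
    assert st_.missing_rate == pytest.approx(0.25)
    assert st_.is_dimorphic


def test_site_stats_monomorphic_and_symmetric():
    rec = IndelRecord.from_alleles("chr1", 9, "A", ["AT"])
    mono = site_stats(rec, [GenotypeCall(str(i), (0, 0)) for i in range(5)])
    assert mono.maf == 0.0 and mono.allele_count == 1 and mono.is_monomorphic
    het = site_stats(rec, [GenotypeCall(str(i), (0, 1)) for i in range(10)])
    assert het.maf == pytest.approx(0.5)


def test_site_stats_all_missing_flagged():
    rec = IndelRecord.from_alleles("chr1", 9, "A", ["AT"])
    st_ = site_stats(rec, [GenotypeCall("a", (None, None))])
    assert st_.missing_rate == 1.0 and math.isnan(st_.maf)


GENOME = {"chr1": "CCGACAAAATGACGTACGTACGT"}


def test_normalize_trims_to_anchor():
    rec = IndelRecord.from_alleles("chr1", 2, "GAC", ["GACAC"])
    norm = normalize_indel(rec, GENOME)
    assert (norm.pos, norm.ref_allele, norm.alt_alleles) == (2, "G", ("GAC",))
    assert norm.length_changes == (2,)


def test_normalize_left_aligns_deletion_in_run():
    # delete one A from the AAAA run at its 3rd position
    rec = IndelRecord.from_alleles("chr1", 7, "AA", ["A"])
    norm = normalize_indel(rec, GENOME)
    assert norm.pos == 4  # anchor C before the run start at 5
    assert (norm.ref_allele, norm.alt_alleles) == ("CA", ("C",))


def test_normalize_identity_and_idempotence():
    rec = IndelRecord.from_alleles("chr1", 9, "TG", ["T"])
    once = normalize_indel(rec, GENOME)
    assert (once.pos, once.ref_allele, once.alt_alleles) == (9, "TG", ("T",))
    assert normalize_indel(once, GENOME) == once


@settings(deadline=None)
@given(st.data())
def test_normalize_idempotent_on_random_indels(data):
    import numpy as np

    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    seq = "".join(rng.choice(list("ACGT"), size=200))
    genome = {"c": seq}
    pos = data.draw(st.integers(20, 150))
    if data.draw(st.booleans()):  # deletion
        size = data.draw(st.integers(1, 8))
        rec = IndelRecord.from_alleles("c", pos, seq[pos : pos + 1 + size],
                                       [seq[pos]])
    else:
        ins = "".join(rng.choice(list("ACGT"),
                                 size=data.draw(st.integers(1, 8))))
        rec = IndelRecord.from_alleles("c", pos, seq[pos], [seq[pos] + ins])
    once = normalize_indel(rec, genome)
    assert normalize_indel(once, genome) == once
    assert once.length_changes == rec.length_changes


def test_normalize_rejects_genome_mismatch():
    rec = IndelRecord.from_alleles("chr1", 0, "TTTT", ["T"])
    with pytest.raises(var.GenomeMismatchError):
        normalize_indel(rec, GENOME)


def test_syri_parsing(tmp_path):
    rows = [
        "chr1\t1000\t1299\t-\t-\tqry1\t1000\t1000\tDEL1\t-\tDEL\t-",
        "chr1\t5000\t9000\t-\t-\tqry1\t5000\t9000\tINV1\t-\tINV\t-",
        "chr1\t2000\t2000\t-\t-\tqry1\t2000\t2001999\tINS1\t-\tINS\t-",
    ]
    path = tmp_path / "syri.tsv"
    path.write_text("\n".join(rows) + "\n")
    out = parse_syri_indels(path)
    assert len(out) == 2
    assert out[0].size_class is SizeClass.LOI
    assert out[0].variant_type is VariantType.DEL
    assert out[0].source is Source.SYRI
    assert out[1].size_class is SizeClass.HOI
    assert out[1].length_changes == (2_000_000,)


def test_syri_bad_layout(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("a\tb\tc\n")
    with pytest.raises(var.SyriFormatError):
        parse_syri_indels(path)


def test_vcf_round_trip(fixture_data, tmp_path):
    """Write accepted records to VCF, re-read, re-normalize: identical."""
    genome = fixture_data["genome"]
    records = fixture_data["records"]
    calls = fixture_data["calls"]
    path = tmp_path / "roundtrip.vcf"
    var.write_vcf(records, calls, {c: len(s) for c, s in genome.items()}, path)
    back = read_vcf_indels(path)
    assert len(back) == len(records)
    for (rec2, calls2), rec1, calls1 in zip(back, records, calls):
        assert normalize_indel(rec2, genome) == rec1
        assert [c.alleles for c in calls2] == [c.alleles for c in calls1]


def test_fixture_class_tallies_match_planted_truth(fixture_data):
    truth = fixture_data["truth"]
    records = fixture_data["records"]
    got = {}
    for rec in records:
        got[rec.size_class.value] = got.get(rec.size_class.value, 0) + 1
    expected = truth["size_class"].value_counts().to_dict()
    assert got == expected
    got_t = {}
    for rec in records:
        got_t[rec.variant_type.value] = got_t.get(rec.variant_type.value, 0) + 1
    assert got_t == truth["variant_type"].value_counts().to_dict()
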