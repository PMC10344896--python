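"""Multi-InDel candidate filtering, grouping, haplotype enumeration, spacing."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omniindel import fixtures as fx
from omniindel.multiindel import (
    MultiIndel,
    candidate_moi_filter,
    count_theoretical_haplotypes,
    design_panel,
    distinct_subset_sums,
    group_windows,
    haplotype_table,
    member_deltas,
    spacing_filter,
    subset_sums,
)
from omniindel.variants import IndelRecord, SiteStats, site_stats


def pairwise_oracle(deltas):
    """Exhaustively compare all 2^k x 2^k subset-sum pairs."""
    sums = []
    for r in range(len(deltas) + 1):
        for combo in itertools.combinations(deltas, r):
            sums.append(sum(combo))
    for i in range(len(sums)):
        for j in range(i + 1, len(sums)):
            if sums[i] == sums[j]:
                return False
    return True


@pytest.mark.parametrize(
    "deltas,expected",
    [
        ([3, 4, 7], False),  # 3 + 4 = 7
        ([1, 2, 4], True),
        ([], True),
        ([3, 5, 9], True),
        ([3, -3], False),
        ([4, 6, 10], False),
    ],
)
def test_distinct_subset_sums_examples(deltas, expected):
    assert distinct_subset_sums(deltas) is expected
    assert pairwise_oracle(deltas) is expected


def test_distinct_subset_sums_rejects_zero():
    with pytest.raises(ValueError):
        distinct_subset_sums([3, 0, 5])


@settings(deadline=None, max_examples=200)
@given(
    st.lists(
        st.integers(3, 10).flatmap(lambda v: st.sampled_from([v, -v])),
        min_size=0, max_size=8,
    )
)
def test_distinct_subset_sums_matches_pairwise_oracle(deltas):
    assert distinct_subset_sums(deltas) is pairwise_oracle(deltas)


@pytest.mark.parametrize("k,expected", [(0, 1), (3, 8), (5, 32), (10, 1024)])
def test_theoretical_haplotype_counts(k, expected):
    assert count_theoretical_haplotypes(k) == expected


def _moi(pos, delta, chrom="c", seq=None):
    if delta > 0:
        return IndelRecord.from_alleles(chrom, pos, "A", ["A" + "C" * delta])
    return IndelRecord.from_alleles(chrom, pos, "A" + "C" * -delta, ["A"])


def test_haplotype_table_enumeration():
    group = [_moi(100, 3), _moi(150, 5), _moi(200, 9)]
    tab = haplotype_table(group)
    assert len(tab) == 8
    assert sorted(tab["length_offset"]) == [0, 3, 5, 8, 9, 12, 14, 17]
    span = group[-1].affected_end - group[0].affected_start
    assert (tab["amplicon_length"] == tab["length_offset"] + span).all()
    assert tab.loc[tab["presence"] == "000", "length_offset"].iloc[0] == 0


def test_haplotype_table_collision_visible():
    tab = haplotype_table([_moi(100, 3), _moi(150, -3)])
    assert len(tab) == 4
    assert sorted(tab["length_offset"]) == [-3, 0, 0, 3]


def test_haplotype_table_rejects_multiallelic():
    bad = IndelRecord.from_alleles("c", 100, "ACC", ["A", "ACCGG"])
    with pytest.raises(ValueError, match="dimorphic"):
        haplotype_table([bad])


def _stats(maf=0.3, missing=0.0, dimorphic=True):
    return SiteStats(2 if dimorphic else 3, maf, missing, dimorphic)


def test_candidate_filter_strict_thresholds():
    recs = [_moi(100, 4), _moi(200, 4), _moi(300, 4), _moi(400, 4)]
    stats = [
        _stats(maf=0.1),            # excluded: maf must exceed 0.1
        _stats(missing=0.5),        # excluded: missing must be below 0.5
        _stats(maf=0.2, missing=0.1),
        _stats(dimorphic=False),    # excluded
    ]
    kept = candidate_moi_filter(recs, stats)
    assert kept == [recs[2]]


def test_candidate_filter_length_range():
    recs = [_moi(100, 2), _moi(200, 3), _moi(300, 10), _moi(400, 11)]
    kept = candidate_moi_filter(recs, [_stats()] * 4)
    assert [r.pos for r in kept] == [200, 300]


def test_group_windows_span_arithmetic():
    # affected spans [100,110), [180,185), [250,255): total 155 <= 200
    recs = [_moi(99, -10), _moi(179, -5), _moi(249, -5)]
    groups = group_windows(recs)
    assert len(groups) == 1 and len(groups[0]) == 3
    span = groups[0][-1].affected_end - groups[0][0].affected_start
    assert span == 155


def test_group_windows_too_few_or_too_wide():
    assert group_windows([_moi(100, 3), _moi(150, 5)]) == []
    wide = [_moi(100, 3), _moi(200, 5), _moi(350, 9)]
    assert group_windows(wide) == []


def test_group_windows_trims_at_k_max():
    recs = [_moi(100 + 20 * i, 3 + i) for i in range(7)]
    groups = group_windows(recs, max_members=5)
    assert len(groups[0]) == 5
    # trimmed members remain available for later groups
    grouped = {r.pos for g in groups for r in g}
    assert grouped <= {r.pos for r in recs}


def test_group_windows_requires_sorted():
    with pytest.raises(ValueError, match="sorted"):
        group_windows([_moi(200, 3), _moi(100, 3)])


def _multi(chrom, start, deltas, spacing=50):
    members = tuple(
        _moi(start + i * spacing, d, chrom=chrom) for i, d in enumerate(deltas)
    )
    return MultiIndel(chrom=chrom, members=members, length_deltas=tuple(deltas))


def test_spacing_filter_symmetric_removal():
    a = _multi("c", 1000, (3, 5, 9))
    b = _multi("c", a.span_end + 150, (4, 7, 9))  # gap 150 <= 200
    assert spacing_filter([a, b]) == []
    c = _multi("c", a.span_end + 201, (4, 7, 9))  # gap 201 > 200
    assert spacing_filter([a, c]) == [a, c]
    assert spacing_filter([a]) == [a]


def test_spacing_filter_different_chromosomes_independent():
    a = _multi("c1", 1000, (3, 5, 9))
    b = _multi("c2", 1050, (4, 7, 9))
    assert spacing_filter([a, b]) == [a, b]


def _six_condition_check(multi, max_span=200, min_members=3,
                         len_range=(3, 10)):
    """Independent re-statement of the six panel conditions."""
    deltas = multi.length_deltas
    assert all(len_range[0] <= abs(d) <= len_range[1] for d in deltas)
    assert multi.k >= min_members
    assert pairwise_oracle(list(deltas))
    assert all(len(m.alt_alleles) == 1 for m in multi.members)
    assert multi.span_length <= max_span
    return True


def test_design_panel_on_planted_fixture(fixture_data):
    records = fixture_data["records"]
    calls = fixture_data["calls"]
    truth = fixture_data["truth"]
    stats = [site_stats(r, c) for r, c in zip(records, calls)]
    design = design_panel(records, stats)
    panel = design["panel"]
    # funnel is monotone
    c = design["counts"]
    assert c["final"] <= c["distinct"] <= c["grouped"] <= c["candidates"]
    # exactly the planted collision-free, well-spaced clusters survive
    expected_ids = sorted(
        truth.loc[truth["expect_in_final"] == True, "multi_id"].unique()  # noqa: E712
    )
    got_members = sorted(
        {tuple(r.pos + 1 for r in m.members) for m in panel}
    )
    expected_members = sorted(
        tuple(g["pos"]) for _, g in
        truth[truth["expect_in_final"] == True].groupby("multi_id")  # noqa: E712
    )
    assert got_members == expected_members
    assert len(expected_ids) == len(panel)
    for m in panel:
        _six_condition_check(m)
    # inter-marker gaps all strictly greater than 200
    for a, b in zip(panel, panel[1:]):
        if a.chrom == b.chrom:
            assert b.span_start - a.span_end > 200


def test_design_panel_deterministic(fixture_data):
    records = fixture_data["records"]
    calls = fixture_data["calls"]
    stats = [site_stats(r, c) for r, c in zip(records, calls)]
    from omniindel.multiindel import panel_table

    t1 = panel_table(design_panel(records, stats)["panel"]).to_csv(index=False)
    t2 = panel_table(design_panel(records, stats)["panel"]).to_csv(index=False)
    assert t1 == t2


@settings(deadline=None, max_examples=20)
@given(st.integers(0, 2**31 - 1))
def test_six_conditions_on_random_fixtures(seed):
    """Every emitted cluster satisfies all panel conditions, checked
    independently of the discovery code, on randomized fixtures."""
    panel = _random_fixture_panel(seed)
    for m in panel:
        _six_condition_check(m)


def _random_fixture_panel(seed, n_clusters=4, genome_length=30_000):
    rng = np.random.default_rng(seed)
    clusters = []
    pos = 2_000
    for _ in range(n_clusters):
        k = int(rng.integers(3, 6))
        deltas = tuple(
            int(rng.integers(3, 11)) * (1 if rng.random() < 0.5 else -1)
            for _ in range(k)
        )
        spacing = int(rng.integers(20, 60))
        positions = tuple(pos + i * spacing for i in range(k))
        clusters.append(
            fx.PlantedCluster(
                positions=positions, deltas=deltas,
                expect_distinct=pairwise_oracle(list(deltas)),
            )
        )
        pos += k * spacing + int(rng.integers(100, 600))
    spec = fx.FixtureSpec(
        genome_length=genome_length, seed=seed, n_samples=40,
        planted_multi_clusters=clusters,
    )
    genome, _ = fx.make_genome(spec)
    records, calls, _ = fx.make_vcf(spec, genome)
    stats = [site_stats(r, c) for r, c in zip(records, calls)]
    return design_panel(records, stats)["panel"]


def test_subset_sums_row_count():
    assert len(subset_sums([3, 5, 9, 11])) == 16
    assert subset_sums([])[0] == ((), 0)


def test_member_deltas_extraction():
    group = [_moi(100, 3), _moi(150, -5)]
    assert member_deltas(group) == (3, -5)
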