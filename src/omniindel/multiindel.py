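"""Multi-InDel panel design.

A Multi-InDel is an ordered cluster of k >= 3 dimorphic medium InDels that
fit in a single <= 200 bp amplicon and whose 2^k theoretical haplotypes —
every presence/absence combination of the member alt alleles — all produce
pairwise-distinct amplicon lengths, so a single size read (capillary
electrophoresis or gel) identifies the haplotype unambiguously.  The length
condition is exactly the distinct-subset-sum property of the member length
deltas.

The panel is built in stages: candidate filter (dimorphic, 3-10 bp,
MAF > 0.1, missing rate < 0.5), greedy left-to-right window grouping
(span <= 200 bp, >= 3 members, up to k_max members), the subset-sum
distinctness test, and finally a symmetric spacing exclusion removing any
pair of accepted clusters closer than 200 bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import pandas as pd

from .variants import IndelRecord, SiteStats

MAX_SPAN = 200
MIN_GAP = 200
MIN_MEMBERS = 3
MAX_MEMBERS = 5
CAND_MAF_MIN = 0.1        # strict: maf must exceed this
CAND_MISSING_MAX = 0.5    # strict: missing rate must be below this
CAND_LEN_RANGE = (3, 10)


@dataclass(frozen=True)
class MultiIndel:
    """An accepted cluster with its haplotype length table precomputed."""

    chrom: str
    members: tuple[IndelRecord, ...]
    length_deltas: tuple[int, ...]

    @property
    def k(self) -> int:
        return len(self.members)

    @property
    def span_start(self) -> int:
        return self.members[0].affected_start

    @property
    def span_end(self) -> int:
        return self.members[-1].affected_end

    @property
    def span_length(self) -> int:
        return self.span_end - self.span_start


def count_theoretical_haplotypes(k: int) -> int:
    """Number of presence/absence haplotypes of a k-member cluster: 2^k."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return 2 ** k


def subset_sums(deltas: Sequence[int]) -> list[tuple[tuple[int, ...], int]]:
    """All (presence vector, sum of selected deltas) pairs, 2^k rows."""
    k = len(deltas)
    out = []
    for mask in range(2 ** k):
        vec = tuple((mask >> i) & 1 for i in range(k))
        out.append((vec, sum(d for d, b in zip(deltas, vec) if b)))
    return out


def distinct_subset_sums(deltas: Sequence[int]) -> bool:
    """True iff all 2^k subset sums of the deltas are pairwise distinct.

    This is the amplicon-length distinctness condition: two haplotypes with
    equal summed deltas are indistinguishable by fragment size.
    """
    if any(d == 0 for d in deltas):
        raise ValueError("zero length delta is not an InDel allele")
    sums = {0}
    for d in deltas:
        new = set()
        for s in sums:
            t = s + d
            if t in sums or t in new:
                return False
            new.add(t)
        if new & sums:
            return False
        sums |= new
    return True


def distinct_subset_sums_bruteforce(deltas: Sequence[int]) -> bool:
    """Pairwise comparison over all 2^k x 2^k haplotype pairs (oracle-grade)."""
    sums = [s for _, s in subset_sums(deltas)]
    return all(a != b for a, b in combinations(sums, 2))


def candidate_moi_filter(
    records: Sequence[IndelRecord],
    stats: Sequence[SiteStats],
    maf_min: float = CAND_MAF_MIN,
    missing_max: float = CAND_MISSING_MAX,
    len_range: tuple[int, int] = CAND_LEN_RANGE,
) -> list[IndelRecord]:
    """Keep dimorphic records with 3-10 bp change, MAF > maf_min (strict)
    and missing rate < missing_max (strict)."""
    lo, hi = len_range
    kept = []
    for rec, st in zip(records, stats):
        if not st.is_dimorphic:
            continue
        if not (lo <= rec.max_abs_change <= hi):
            continue
        if not (st.maf == st.maf and st.maf > maf_min):
            continue
        if not st.missing_rate < missing_max:
            continue
        kept.append(rec)
    return kept


def group_windows(
    candidates: Sequence[IndelRecord],
    max_span: int = MAX_SPAN,
    min_members: int = MIN_MEMBERS,
    max_members: int = MAX_MEMBERS,
) -> list[list[IndelRecord]]:
    """Greedy left-to-right maximal grouping of sorted candidates.

    Starting at each ungrouped leftmost candidate, extend rightward while
    the span (first member's affected start to last member's affected end)
    stays within ``max_span``.  Groups with >= ``min_members`` are emitted;
    groups larger than ``max_members`` are trimmed from the right, and the
    trimmed candidates may seed subsequent groups.
    """
    for a, b in zip(candidates, candidates[1:]):
        if (a.chrom, a.pos) > (b.chrom, b.pos):
            raise ValueError("candidates must be sorted by chromosome, position")
    groups: list[list[IndelRecord]] = []
    i = 0
    n = len(candidates)
    while i < n:
        first = candidates[i]
        j = i + 1
        while (
            j < n
            and candidates[j].chrom == first.chrom
            and candidates[j].affected_end - first.affected_start <= max_span
            and (j - i) < max_members
        ):
            j += 1
        group = list(candidates[i:j])
        if len(group) >= min_members:
            groups.append(group)
            i = j
        else:
            i += 1
    return groups


def haplotype_table(group: Sequence[IndelRecord] | "MultiIndel") -> pd.DataFrame:
    """Enumerate all 2^k theoretical haplotypes of a cluster.

    Columns: ``presence`` (e.g. "101"), ``length_offset`` (sum of selected
    deltas) and ``amplicon_length`` (reference span + offset).
    """
    if isinstance(group, MultiIndel):
        members = group.members
    else:
        members = tuple(group)
    deltas = []
    for rec in members:
        nonzero = [c for c in rec.length_changes if c != 0]
        if len(rec.alt_alleles) != 1 or len(nonzero) != 1:
            raise ValueError(
                f"non-dimorphic member at {rec.chrom}:{rec.pos + 1}"
            )
        deltas.append(nonzero[0])
    span = members[-1].affected_end - members[0].affected_start
    rows = [
        {
            "presence": "".join(str(b) for b in vec),
            "length_offset": s,
            "amplicon_length": span + s,
        }
        for vec, s in subset_sums(deltas)
    ]
    return pd.DataFrame(rows, columns=["presence", "length_offset",
                                       "amplicon_length"])


def member_deltas(group: Sequence[IndelRecord]) -> tuple[int, ...]:
    deltas = []
    for rec in group:
        nonzero = [c for c in rec.length_changes if c != 0]
        if len(rec.alt_alleles) != 1 or len(nonzero) != 1:
            raise ValueError(f"non-dimorphic member at {rec.chrom}:{rec.pos + 1}")
        deltas.append(nonzero[0])
    return tuple(deltas)


def spacing_filter(
    multis: Sequence[MultiIndel], min_gap: int = MIN_GAP
) -> list[MultiIndel]:
    """Symmetric spacing exclusion: drop BOTH clusters of any adjacent pair
    whose gap (next span_start - previous span_end) is <= ``min_gap``."""
    multis = sorted(multis, key=lambda m: (m.chrom, m.span_start))
    too_close = [False] * len(multis)
    for idx in range(len(multis) - 1):
        a, b = multis[idx], multis[idx + 1]
        if a.chrom != b.chrom:
            continue
        gap = b.span_start - a.span_end
        if gap <= min_gap:
            too_close[idx] = True
            too_close[idx + 1] = True
    return [m for m, drop in zip(multis, too_close) if not drop]


def design_panel(
    records: Sequence[IndelRecord],
    stats: Sequence[SiteStats],
    maf_min: float = CAND_MAF_MIN,
    missing_max: float = CAND_MISSING_MAX,
    len_range: tuple[int, int] = CAND_LEN_RANGE,
    max_span: int = MAX_SPAN,
    min_gap: int = MIN_GAP,
    min_members: int = MIN_MEMBERS,
    max_members: int = MAX_MEMBERS,
) -> dict:
    """Run the full design funnel; returns panel plus per-stage counts."""
    order = sorted(range(len(records)),
                   key=lambda i: (records[i].chrom, records[i].pos))
    records = [records[i] for i in order]
    stats = [stats[i] for i in order]
    candidates = candidate_moi_filter(
        records, stats, maf_min=maf_min, missing_max=missing_max,
        len_range=len_range,
    )
    groups = group_windows(
        candidates, max_span=max_span, min_members=min_members,
        max_members=max_members,
    )
    accepted = []
    for group in groups:
        deltas = member_deltas(group)
        if distinct_subset_sums(deltas):
            accepted.append(
                MultiIndel(chrom=group[0].chrom, members=tuple(group),
                           length_deltas=deltas)
            )
    panel = spacing_filter(accepted, min_gap=min_gap)
    return {
        "panel": panel,
        "counts": {
            "input": len(records),
            "candidates": len(candidates),
            "grouped": len(groups),
            "distinct": len(accepted),
            "final": len(panel),
        },
    }


def panel_table(panel: Sequence[MultiIndel]) -> pd.DataFrame:
    rows = [
        {
            "chrom": m.chrom,
            "span_start": m.span_start,
            "span_end": m.span_end,
            "span_length": m.span_length,
            "k": m.k,
            "member_positions": ",".join(str(r.pos + 1) for r in m.members),
            "length_deltas": ",".join(str(d) for d in m.length_deltas),
        }
        for m in panel
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "span_start", "span_end", "span_length", "k",
                 "member_positions", "length_deltas"],
    )


def panel_haplotype_table(panel: Sequence[MultiIndel]) -> pd.DataFrame:
    frames = []
    for i, m in enumerate(panel):
        tab = haplotype_table(m)
        tab.insert(0, "multi_id", f"{m.chrom}_{m.span_start}")
        frames.append(tab)
    if not frames:
        return pd.DataFrame(
            columns=["multi_id", "presence", "length_offset", "amplicon_length"]
        )
    return pd.concat(frames, ignore_index=True)


def panel_bed(panel: Sequence[MultiIndel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": m.chrom, "start": m.span_start, "end": m.span_end,
             "name": f"{m.chrom}_{m.span_start}", "k": m.k}
            for m in panel
        ],
        columns=["chrom", "start", "end", "name", "k"],
    )
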