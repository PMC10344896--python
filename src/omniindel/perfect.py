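"""Perfect InDel filtering.

A "Perfect InDel" is a marker-grade site: a dimorphic 3-10 bp InDel with a
minor allele frequency of at least 0.05 whose 30-bp flank on at least one
side occurs exactly once in the genome (counting both strands), so that a
locus-specific assay (PAGE, capillary electrophoresis, KASP, sequencing)
can anchor on it.

Flank uniqueness here is by exact string matching on both strands — a
deterministic, conservative stand-in for an alignment-based screen.  An
optional edit-distance-1 neighborhood mode tightens it further.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import GenomeMismatchError, IndelRecord, SiteStats

FLANK_LENGTH = 30
MIN_FLANK_LENGTH = 12  # below this, exact counts are dominated by chance hits

_COMP = str.maketrans("ACGTN", "TGCAN")

#: sentinel copy number for flanks that cannot be counted reliably
AMBIGUOUS = -1

#: verdict labels, in filter order; the verdict records the FIRST failure
CRITERIA = ("length", "dimorphic", "flank", "maf")
PASS = "pass"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class PerfectIndel:
    record: IndelRecord
    left_flank: str
    right_flank: str
    left_copy_number: int
    right_copy_number: int
    verdict: str  # "pass" or the first failing criterion

    @property
    def passed(self) -> bool:
        return self.verdict == PASS


def extract_flanks(
    genome: Mapping[str, str], record: IndelRecord, k: int = FLANK_LENGTH
) -> tuple[str, str]:
    """Reference-strand k-mers immediately left/right of the affected interval.

    A variant within k bases of a contig end yields a truncated flank; the
    uniqueness test treats truncated flanks as ambiguous (never unique).
    """
    if k < 1:
        raise ValueError("flank length must be >= 1")
    seq = genome[record.chrom].upper()
    a0, a1 = record.affected_interval
    left = seq[max(0, a0 - k) : a0]
    right = seq[a1 : a1 + k]
    return left, right


def count_occurrences(haystack: str, needle: str) -> int:
    """Overlap-counting exact occurrences of needle in haystack."""
    count = 0
    i = haystack.find(needle)
    while i != -1:
        count += 1
        i = haystack.find(needle, i + 1)
    return count


def flank_copy_number(
    genome: Mapping[str, str] | str, flank_seq: str, min_len: int = MIN_FLANK_LENGTH
) -> int:
    """Exact occurrences of a flank in the genome over both strands.

    Forward hits plus reverse-complement hits; the flank's own source locus
    contributes one.  A flank containing N, or shorter than ``min_len``
    (e.g. truncated at a contig end), returns the AMBIGUOUS sentinel.
    """
    flank = flank_seq.upper()
    if len(flank) < min_len or "N" in flank:
        return AMBIGUOUS
    rc = reverse_complement(flank)
    seqs = [genome.upper()] if isinstance(genome, str) else [
        genome[c].upper() for c in genome
    ]
    total = 0
    for seq in seqs:
        total += count_occurrences(seq, flank) + count_occurrences(seq, rc)
    return total


def _neighborhood_unique(genome: Mapping[str, str] | str, flank: str) -> bool:
    """True if no edit-distance-1 variant of the flank occurs elsewhere.

    Optional stricter screen: substitution neighbors only (length-preserving),
    both strands.  Quadratic in genome size; intended for small references.
    """
    seqs = [genome] if isinstance(genome, str) else [genome[c] for c in genome]
    flank = flank.upper()
    rc = reverse_complement(flank)
    k = len(flank)
    exact = 0
    near = 0
    for seq in seqs:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            for target in (flank, rc):
                d = sum(1 for x, y in zip(window, target) if x != y)
                if d == 0:
                    exact += 1
                elif d == 1:
                    near += 1
            if rc == flank:
                break
    return exact == 1 and near == 0


def evaluate_perfect(
    record: IndelRecord,
    stats: SiteStats,
    genome: Mapping[str, str],
    maf_min: float = 0.05,
    len_range: tuple[int, int] = (3, 10),
    flank_len: int = FLANK_LENGTH,
    strict_neighborhood: bool = False,
) -> PerfectIndel:
    """Apply the marker-grade criteria in fixed order and record the verdict.

    Order: length in range -> dimorphic -> at least one single-copy flank ->
    MAF >= maf_min (inclusive).  The verdict is "pass" or the first failure.
    """
    seq = genome[record.chrom].upper()
    if seq[record.pos : record.pos + len(record.ref_allele)] != record.ref_allele:
        raise GenomeMismatchError(
            f"record at {record.chrom}:{record.pos + 1} disagrees with genome"
        )
    left, right = extract_flanks(genome, record, k=flank_len)
    lcn = flank_copy_number(genome, left) if len(left) == flank_len else AMBIGUOUS
    rcn = flank_copy_number(genome, right) if len(right) == flank_len else AMBIGUOUS

    lo, hi = len_range
    verdict = PASS
    if not (lo <= record.max_abs_change <= hi):
        verdict = "length"
    elif not stats.is_dimorphic:
        verdict = "dimorphic"
    else:
        unique = (lcn == 1) or (rcn == 1)
        if unique and strict_neighborhood:
            unique = any(
                cn == 1 and _neighborhood_unique(genome, fl)
                for cn, fl in ((lcn, left), (rcn, right))
            )
        if not unique:
            verdict = "flank"
        elif not (stats.maf == stats.maf and stats.maf >= maf_min):
            verdict = "maf"
    return PerfectIndel(record, left, right, lcn, rcn, verdict)


def filter_perfect(
    records: Sequence[IndelRecord],
    stats: Sequence[SiteStats],
    genome: Mapping[str, str],
    maf_min: float = 0.05,
    len_range: tuple[int, int] = (3, 10),
    flank_len: int = FLANK_LENGTH,
    strict_neighborhood: bool = False,
) -> list[PerfectIndel]:
    """Evaluate every record; returns all, sorted by position, with verdicts."""
    if len(records) != len(stats):
        raise ValueError("records and stats must be parallel sequences")
    out = [
        evaluate_perfect(
            rec, st, genome, maf_min=maf_min, len_range=len_range,
            flank_len=flank_len, strict_neighborhood=strict_neighborhood,
        )
        for rec, st in zip(records, stats)
    ]
    out.sort(key=lambda p: (p.record.chrom, p.record.pos))
    return out


def perfect_table(results: Sequence[PerfectIndel]) -> pd.DataFrame:
    rows = []
    for p in results:
        rec = p.record
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos + 1,
                "ref": rec.ref_allele,
                "alts": ",".join(rec.alt_alleles),
                "size_class": rec.size_class.value,
                "variant_type": rec.variant_type.value,
                "left_flank": p.left_flank,
                "right_flank": p.right_flank,
                "left_copy_number": p.left_copy_number,
                "right_copy_number": p.right_copy_number,
                "verdict": p.verdict,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alts", "size_class", "variant_type",
            "left_flank", "right_flank", "left_copy_number",
            "right_copy_number", "verdict",
        ],
    )


def flank_fasta(results: Sequence[PerfectIndel]) -> str:
    """FASTA of passing sites' flanks, for external primer design."""
    chunks = []
    for p in results:
        if not p.passed:
            continue
        tag = f"{p.record.chrom}_{p.record.pos + 1}"
        chunks.append(f">{tag}_L\n{p.left_flank}\n>{tag}_R\n{p.right_flank}\n")
    return "".join(chunks)


def missingness_report(
    codes: np.ndarray,
    sample_ids: Sequence[str] | None = None,
    locus_ids: Sequence[str] | None = None,
) -> dict:
    """Per-sample and per-site missingness of a coded genotype matrix.

    ``codes`` is samples x loci with NaN marking missing cells.  Returns
    per-sample counts/rates, per-site rates, and min/mean sample summaries.
    """
    codes = np.asarray(codes, dtype=float)
    if codes.size == 0:
        raise ValueError("empty genotype matrix")
    n_samples, n_loci = codes.shape
    sample_ids = list(sample_ids) if sample_ids is not None else [
        f"S{i}" for i in range(n_samples)
    ]
    locus_ids = list(locus_ids) if locus_ids is not None else [
        f"L{i}" for i in range(n_loci)
    ]
    miss = np.isnan(codes)
    per_sample = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "missing_count": miss.sum(axis=1),
            "missing_rate": miss.mean(axis=1),
        }
    )
    per_site = pd.DataFrame(
        {"locus_id": locus_ids, "missing_rate": miss.mean(axis=0)}
    )
    return {
        "per_sample": per_sample,
        "per_site": per_site,
        "min_sample_missing": int(per_sample["missing_count"].min()),
        "mean_sample_missing": float(per_sample["missing_count"].mean()),
        "mean_sample_missing_rate": float(per_sample["missing_rate"].mean()),
    }
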