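"""Microsatellite (SSR) scanning and dual SSR/InDel classification.

A simple sequence repeat is a maximal perfect tandem run of a 1-6 bp motif
meeting a per-motif-length minimum copy number.  The default minima follow
the common MISA parameterization for crop genomes: 10 copies for
mononucleotide motifs, 6 for dinucleotide, 5 for trinucleotide, 4 for
tetranucleotide and 3 for penta-/hexanucleotide motifs.

An InDel whose affected reference interval touches an SSR locus is an
"SSR-InDel"; when every inserted/deleted sequence is additionally a whole
number of motif copies the site is motif-consistent — the allele series
then behaves like an SSR length ladder.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .variants import IndelRecord

#: minimum copy number by motif length (MISA-style)
DEFAULT_THRESHOLDS: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 4, 5: 3, 6: 3}

_VALID = set("ACGTN")


class SsrScanError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class SsrLocus:
    """A maximal perfect tandem repeat run (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    motif: str  # canonical (lexicographically smallest rotation)
    repeat_count: int

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.motif) * self.repeat_count:
            raise ValueError("interval length must equal motif x repeat_count")

    @property
    def period(self) -> int:
        return len(self.motif)


class SsrIndelClass(str, enum.Enum):
    NON_SSR = "NON_SSR"
    SSR_OVERLAP = "SSR_OVERLAP"
    SSR_MOTIF_CONSISTENT = "SSR_MOTIF_CONSISTENT"


def canonical_motif(motif: str) -> str:
    """Lexicographically smallest rotation; reverse complement not merged."""
    if not motif:
        raise ValueError("empty motif")
    rotations = (motif[i:] + motif[:i] for i in range(len(motif)))
    return min(rotations)


def _min_period(s: str) -> int:
    """Smallest p such that s is a whole number of copies of s[:p]."""
    n = len(s)
    for p in range(1, n + 1):
        if n % p == 0 and s[: p] * (n // p) == s:
            return p
    return n


def scan_ssrs(
    sequence: str,
    thresholds: Mapping[int, int] | None = None,
    chrom: str = "chr",
    offset: int = 0,
) -> list[SsrLocus]:
    """Find all maximal perfect SSR runs meeting the copy-number thresholds.

    A run is reported at its shortest period only (an AT run never doubles
    as an ATAT run) and is maximal: not extendable by a full motif copy on
    either side.  Trailing partial copies are not counted.  N breaks runs;
    characters outside ACGTN raise :class:`SsrScanError`.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    seq = sequence.upper()
    bad = set(seq) - _VALID
    if bad:
        raise SsrScanError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    n = len(seq)
    loci: list[SsrLocus] = []
    for period, min_copies in sorted(thresholds.items()):
        i = 0
        while i + period < n:
            if seq[i] == "N" or seq[i + period] != seq[i]:
                i += 1
                continue
            # extend the match run seq[j] == seq[j+period]
            j = i
            while j + period < n and seq[j + period] == seq[j] and seq[j] != "N":
                j += 1
            run_len = (j - i) + period  # total periodic stretch length
            copies = run_len // period
            motif = seq[i : i + period]
            if copies >= min_copies and _min_period(motif) == period:
                loci.append(
                    SsrLocus(
                        chrom=chrom,
                        start=offset + i,
                        end=offset + i + copies * period,
                        motif=canonical_motif(motif),
                        repeat_count=copies,
                    )
                )
            i = j + 1
    loci.sort(key=lambda l: (l.start, l.period))
    return loci


def scan_genome_ssrs(
    genome: Mapping[str, str],
    thresholds: Mapping[int, int] | None = None,
) -> list[SsrLocus]:
    out: list[SsrLocus] = []
    for chrom in genome:
        out.extend(scan_ssrs(genome[chrom], thresholds, chrom=chrom))
    return out


def _overlaps(record: IndelRecord, locus: SsrLocus) -> bool:
    a0, a1 = record.affected_interval
    if a0 == a1:  # pure insertion: point; boundary contact counts
        return locus.start <= a0 <= locus.end
    return a0 < locus.end and a1 > locus.start


def _delta_seq(ref: str, alt: str) -> str | None:
    """Pure inserted/deleted sequence after stripping shared prefix+suffix.

    Returns None when the pair is not a clean insertion or deletion (both
    sides retain sequence after trimming).
    """
    i = 0
    while i < min(len(ref), len(alt)) and ref[i] == alt[i]:
        i += 1
    r, a = ref[i:], alt[i:]
    j = 0
    while j < min(len(r), len(a)) and r[len(r) - 1 - j] == a[len(a) - 1 - j]:
        j += 1
    r = r[: len(r) - j]
    a = a[: len(a) - j]
    if r and a:
        return None
    return r or a


def _motif_consistent(record: IndelRecord, locus: SsrLocus) -> bool:
    period = locus.period
    for alt, change in zip(record.alt_alleles, record.length_changes):
        if change == 0:
            continue
        seq = _delta_seq(record.ref_allele, alt)
        if seq is None or len(seq) % period != 0:
            return False
        copies = len(seq) // period
        rotations = {locus.motif[i:] + locus.motif[:i] for i in range(period)}
        if not any(rot * copies == seq for rot in rotations):
            return False
    return True


def classify_ssr_indel(
    record: IndelRecord, ssr_loci: Sequence[SsrLocus]
) -> SsrIndelClass:
    """Classify a normalized InDel against SSR loci from the same genome.

    NON_SSR when the affected interval touches no locus; SSR_OVERLAP when it
    does; SSR_MOTIF_CONSISTENT when additionally every length-changing
    allele is an exact whole number of copies of a rotation of an
    overlapped locus' motif.
    """
    prev_start = None
    for locus in ssr_loci:
        if prev_start is not None and locus.start < prev_start:
            raise ValueError("ssr_loci must be sorted by start position")
        prev_start = locus.start
    hit = [
        loc for loc in ssr_loci
        if loc.chrom == record.chrom and _overlaps(record, loc)
    ]
    if not hit:
        return SsrIndelClass.NON_SSR
    if any(_motif_consistent(record, loc) for loc in hit):
        return SsrIndelClass.SSR_MOTIF_CONSISTENT
    return SsrIndelClass.SSR_OVERLAP


def ssr_indel_summary(
    records: Sequence[IndelRecord], ssr_loci: Sequence[SsrLocus]
) -> pd.DataFrame:
    """Per-chromosome and per-motif-length SSR counts and InDel overlap rates.

    One row per (chrom, motif length): number of SSR loci, how many are
    overlapped by at least one InDel, how many of those overlaps are
    motif-consistent, and the overlapped fraction.
    """
    overlapped: set[SsrLocus] = set()
    consistent: set[SsrLocus] = set()
    by_chrom: dict[str, list[SsrLocus]] = {}
    for loc in ssr_loci:
        by_chrom.setdefault(loc.chrom, []).append(loc)
    for rec in records:
        for loc in by_chrom.get(rec.chrom, ()):
            if _overlaps(rec, loc):
                overlapped.add(loc)
                if _motif_consistent(rec, loc):
                    consistent.add(loc)
    rows = []
    keys = sorted({(l.chrom, l.period) for l in ssr_loci})
    for chrom, period in keys:
        group = [l for l in ssr_loci if l.chrom == chrom and l.period == period]
        n_hit = sum(1 for l in group if l in overlapped)
        rows.append(
            {
                "chrom": chrom,
                "motif_length": period,
                "n_ssr": len(group),
                "n_overlapped": n_hit,
                "n_motif_consistent": sum(1 for l in group if l in consistent),
                "fraction_overlapped": n_hit / len(group),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "motif_length", "n_ssr", "n_overlapped",
            "n_motif_consistent", "fraction_overlapped",
        ],
    )


def loci_table(loci: Iterable[SsrLocus]) -> pd.DataFrame:
    """BED-like table of SSR loci (0-based half-open)."""
    return pd.DataFrame(
        [
            {
                "chrom": l.chrom,
                "start": l.start,
                "end": l.end,
                "motif": l.motif,
                "repeat_count": l.repeat_count,
            }
            for l in loci
        ],
        columns=["chrom", "start", "end", "motif", "repeat_count"],
    )
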