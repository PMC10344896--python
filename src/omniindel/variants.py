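"""Core InDel data model: VCF/SyRI ingestion, normalization and classification.

An "Omni InDel" site is any variant site at which at least one alternate
allele differs in length from the reference allele.  Sites are partitioned
by the magnitude of the largest length change into four size classes —
small (SOI, 1-2 bp), medium (MOI, 3-49 bp), large (LOI, 50-999 bp) and huge
(HOI, >= 1000 bp) — and into three types: insertion (all alleles gain
sequence), deletion (all alleles lose sequence) or mixed (a multi-allelic
site carrying both an insertion and a deletion allele).

Coordinates are 0-based half-open internally; VCF input/output is 1-based.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam


class SizeClass(str, enum.Enum):
    SOI = "SOI"
    MOI = "MOI"
    LOI = "LOI"
    HOI = "HOI"


class VariantType(str, enum.Enum):
    INS = "INS"
    DEL = "DEL"
    MIXED = "MIXED"


class Source(str, enum.Enum):
    VCF = "VCF"
    SYRI = "SYRI"


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be parsed."""


class GenomeMismatchError(ValueError):
    """Raised when a record's reference allele disagrees with the genome."""


class SyriFormatError(ValueError):
    """Raised when a SyRI-style table has an unrecognized column layout."""


MISSING = None  # missing allele index inside a GenotypeCall


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's diploid call at a site; missing alleles are None."""

    sample_id: str
    alleles: tuple[int | None, int | None]

    @property
    def is_missing(self) -> bool:
        return self.alleles[0] is None or self.alleles[1] is None


@dataclass(frozen=True)
class IndelRecord:
    """One normalized variant site with per-alt length changes.

    ``pos`` is a 0-based reference coordinate.  For VCF-derived records the
    alleles are explicit sequences; SyRI-derived large variants may carry an
    empty alt for a deletion, with ``length_changes`` authoritative.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    length_changes: tuple[int, ...]
    size_class: SizeClass
    variant_type: VariantType
    source: Source = Source.VCF

    @classmethod
    def from_alleles(
        cls,
        chrom: str,
        pos: int,
        ref: str,
        alts: Sequence[str],
        source: Source = Source.VCF,
    ) -> "IndelRecord":
        alts = tuple(a.upper() for a in alts)
        ref = ref.upper()
        for a in alts:
            if a == ref:
                raise ValueError(f"alt allele identical to ref at {chrom}:{pos + 1}")
        changes = tuple(len(a) - len(ref) for a in alts)
        if all(c == 0 for c in changes):
            raise ValueError(f"no length change at {chrom}:{pos + 1}: not an InDel")
        return cls(
            chrom=chrom,
            pos=pos,
            ref_allele=ref,
            alt_alleles=alts,
            length_changes=changes,
            size_class=classify_size(max(abs(c) for c in changes if c != 0)),
            variant_type=classify_type_from_changes(changes),
            source=source,
        )

    @property
    def max_abs_change(self) -> int:
        return max(abs(c) for c in self.length_changes if c != 0)

    @property
    def is_anchored(self) -> bool:
        """True when ref and all alts share a leading anchor base."""
        return bool(self.ref_allele) and all(
            a and a[0] == self.ref_allele[0] for a in self.alt_alleles
        )

    @property
    def affected_start(self) -> int:
        """Start (0-based) of the reference interval altered by the variant."""
        return self.pos + 1 if self.is_anchored else self.pos

    @property
    def affected_end(self) -> int:
        """End (0-based, exclusive); equals start for a pure insertion."""
        return self.pos + len(self.ref_allele)

    @property
    def affected_interval(self) -> tuple[int, int]:
        return self.affected_start, self.affected_end


def classify_size(max_abs_length_change: int) -> SizeClass:
    """Assign a size class from the largest absolute length change (bp).

    Half-open boundaries: [1,3) SOI, [3,50) MOI, [50,1000) LOI, [1000,inf) HOI.
    """
    n = int(max_abs_length_change)
    if n < 1:
        raise ValueError("length change of 0 bp is not an InDel")
    if n < 3:
        return SizeClass.SOI
    if n < 50:
        return SizeClass.MOI
    if n < 1000:
        return SizeClass.LOI
    return SizeClass.HOI


def classify_type_from_changes(length_changes: Sequence[int]) -> VariantType:
    nonzero = [c for c in length_changes if c != 0]
    if not nonzero:
        raise ValueError("all length changes are zero: not an InDel")
    if all(c > 0 for c in nonzero):
        return VariantType.INS
    if all(c < 0 for c in nonzero):
        return VariantType.DEL
    return VariantType.MIXED


def classify_type(record: IndelRecord) -> VariantType:
    """INS if every allele inserts, DEL if every allele deletes, else MIXED."""
    return classify_type_from_changes(record.length_changes)


@dataclass(frozen=True)
class SiteStats:
    """Allele-frequency summary of one site over the genotyped samples.

    ``maf`` is the frequency of the second-most-frequent observed allele
    (the minor allele at a dimorphic site), computed over non-missing calls;
    it is NaN when every call is missing.
    """

    allele_count: int
    maf: float
    missing_rate: float
    is_dimorphic: bool

    @property
    def is_monomorphic(self) -> bool:
        return self.allele_count <= 1

    @property
    def all_missing(self) -> bool:
        return self.missing_rate >= 1.0


def site_stats(record: IndelRecord, calls: Sequence[GenotypeCall]) -> SiteStats:
    """Compute allele count, MAF and missing rate from diploid calls.

    A genotype with any missing allele counts as a missing sample; allele
    frequencies are taken over the remaining 2n allele observations.
    """
    if not calls:
        raise ValueError("site_stats requires at least one sample")
    n_missing = 0
    counts: dict[int, int] = {}
    for call in calls:
        if call.is_missing:
            n_missing += 1
            continue
        for a in call.alleles:
            if a < 0 or a > len(record.alt_alleles):
                raise ValueError(
                    f"allele index {a} out of range at {record.chrom}:{record.pos + 1}"
                )
            counts[a] = counts.get(a, 0) + 1
    missing_rate = n_missing / len(calls)
    total = sum(counts.values())
    if total == 0:
        return SiteStats(allele_count=0, maf=float("nan"), missing_rate=1.0,
                         is_dimorphic=False)
    freqs = sorted((c / total for c in counts.values()), reverse=True)
    maf = freqs[1] if len(freqs) >= 2 else 0.0
    return SiteStats(
        allele_count=len(counts),
        maf=maf,
        missing_rate=missing_rate,
        is_dimorphic=len(counts) == 2,
    )


def _has_length_change(ref: str, alts: Iterable[str]) -> bool:
    return any(len(a) != len(ref) for a in alts)


def read_vcf_indels(
    vcf_path: str | Path,
) -> list[tuple[IndelRecord, list[GenotypeCall]]]:
    """Read a VCF and keep only sites with at least one length-changing alt.

    SNP-only sites are dropped.  Multi-allelic sites are kept as single
    records with per-alt length changes.  A record whose FORMAT lacks GT is
    retained with all-missing genotypes and a warning.
    """
    out: list[tuple[IndelRecord, list[GenotypeCall]]] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        line_no = len(str(vcf.header).rstrip("\n").split("\n"))
        for rec in vcf:
            line_no += 1
            try:
                if rec.alts is None:
                    continue
                alts = [a for a in rec.alts if a is not None and _is_seq(a)]
                if not alts or not _has_length_change(rec.ref, alts):
                    continue
                record = IndelRecord.from_alleles(
                    rec.chrom, rec.start, rec.ref, alts, source=Source.VCF
                )
                calls: list[GenotypeCall] = []
                has_gt = "GT" in rec.format
                if samples and not has_gt:
                    warnings.warn(
                        f"no GT field at {rec.chrom}:{rec.pos}; "
                        "genotypes set to missing"
                    )
                for s in samples:
                    if has_gt:
                        gt = rec.samples[s].get("GT", (None, None))
                        if gt is None or len(gt) == 0:
                            gt = (None, None)
                        elif len(gt) == 1:  # haploid call, duplicate
                            gt = (gt[0], gt[0])
                    else:
                        gt = (None, None)
                    calls.append(GenotypeCall(s, (gt[0], gt[1])))
                out.append((record, calls))
            except Exception as exc:  # noqa: BLE001 - rewrap with location
                raise VcfParseError(
                    f"malformed VCF record near line {line_no}: {exc}"
                ) from exc
    return out


def _is_seq(allele: str) -> bool:
    return bool(allele) and not allele.startswith("<") and allele != "*"


def normalize_indel(record: IndelRecord, genome: Mapping[str, str]) -> IndelRecord:
    """Left-align and trim a record to its minimal anchored representation.

    Shared trailing bases are stripped (borrowing reference bases on the
    left when an allele would empty, which shifts the variant leftward
    through repeat runs), then shared leading bases are stripped down to a
    single anchor base.  Idempotent.
    """
    seq = genome[record.chrom].upper()
    pos = record.pos
    ref = record.ref_allele
    alts = list(record.alt_alleles)
    if seq[pos : pos + len(ref)] != ref:
        raise GenomeMismatchError(
            f"reference allele disagrees with genome at {record.chrom}:{pos + 1}"
        )
    alleles = [ref] + alts
    # Right-trim with left extension: classic left-alignment loop.
    while True:
        if all(a for a in alleles) and len({a[-1] for a in alleles}) == 1 and (
            len(alleles[0]) > 1 or any(len(a) > 1 for a in alleles[1:])
        ):
            alleles = [a[:-1] for a in alleles]
        elif any(not a for a in alleles):
            if pos == 0:
                # Cannot extend further left; re-anchor on the right instead.
                base = seq[pos + len(alleles[0])]
                alleles = [a + base for a in alleles]
                break
            pos -= 1
            base = seq[pos]
            alleles = [base + a for a in alleles]
        else:
            break
    # Left-trim down to one shared anchor base.
    while (
        len(alleles[0]) > 1
        and all(len(a) > 1 for a in alleles[1:])
        and len({a[0] for a in alleles}) == 1
    ):
        alleles = [a[1:] for a in alleles]
        pos += 1
    new = IndelRecord.from_alleles(
        record.chrom, pos, alleles[0], alleles[1:], source=record.source
    )
    return new


def parse_syri_indels(syri_path: str | Path) -> list[IndelRecord]:
    """Extract insertion/deletion rows from a SyRI-style annotation table.

    Expects the 12-column headerless layout (ref chrom/start/end/seq, query
    seq/chrom/start/end, id, parent, annotation type, copy status); only rows
    whose annotation type is INS or DEL become records, everything else
    (SYN, INV, TRANS, DUP, SNP, CPG, CPL, ...) is ignored.  Coordinates in
    the table are 1-based inclusive.
    """
    rows = pd.read_csv(syri_path, sep="\t", header=None, dtype=str,
                       keep_default_na=False)
    if rows.shape[1] < 11:
        raise SyriFormatError(
            f"expected >=11 tab-separated columns, found {rows.shape[1]}"
        )
    out: list[IndelRecord] = []
    for row in rows.itertuples(index=False):
        vtype = row[10].strip().upper()
        if vtype not in ("INS", "DEL"):
            continue
        chrom = row[0]
        start = int(row[1])
        ref_seq = row[3] if set(row[3]) <= set("ACGTN") and row[3] else ""
        alt_seq = row[4] if set(row[4]) <= set("ACGTN") and row[4] else ""
        if vtype == "DEL":
            length = int(row[2]) - start + 1
            ref = ref_seq or "N" * length
            alt = ""
            changes = (-length,)
        else:
            length = int(row[7]) - int(row[6]) + 1
            ref = ref_seq
            alt = alt_seq or "N" * length
            changes = (length,)
        out.append(
            IndelRecord(
                chrom=chrom,
                pos=start - 1,
                ref_allele=ref,
                alt_alleles=(alt,),
                length_changes=changes,
                size_class=classify_size(length),
                variant_type=VariantType[vtype],
                source=Source.SYRI,
            )
        )
    return out


def classification_table(
    records: Sequence[IndelRecord],
    stats: Sequence[SiteStats] | None = None,
) -> pd.DataFrame:
    """Tabulate records (1-based positions) with optional per-site stats."""
    rows = []
    for i, rec in enumerate(records):
        row = {
            "chrom": rec.chrom,
            "pos": rec.pos + 1,
            "ref": rec.ref_allele,
            "alts": ",".join(rec.alt_alleles),
            "length_changes": ",".join(str(c) for c in rec.length_changes),
            "size_class": rec.size_class.value,
            "variant_type": rec.variant_type.value,
            "source": rec.source.value,
        }
        if stats is not None:
            st = stats[i]
            row.update(
                allele_count=st.allele_count,
                maf=round(st.maf, 6) if st.maf == st.maf else float("nan"),
                missing_rate=round(st.missing_rate, 6),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_vcf(
    records: Sequence[IndelRecord],
    calls: Sequence[Sequence[GenotypeCall]] | None,
    contigs: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write records (and optional genotypes) as a plain-text VCF v4.2."""
    sample_ids: list[str] = []
    if calls is not None and calls and calls[0]:
        sample_ids = [c.sample_id for c in calls[0]]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if sample_ids:
            header += ["FORMAT"] + sample_ids
        fh.write("\t".join(header) + "\n")
        order = sorted(range(len(records)),
                       key=lambda i: (records[i].chrom, records[i].pos))
        for i in order:
            rec = records[i]
            fields = [
                rec.chrom,
                str(rec.pos + 1),
                ".",
                rec.ref_allele,
                ",".join(rec.alt_alleles),
                ".",
                "PASS",
                ".",
            ]
            if sample_ids:
                fields.append("GT")
                for call in calls[i]:
                    a, b = call.alleles
                    fields.append(
                        "./." if call.is_missing else f"{a}/{b}"
                    )
            fh.write("\t".join(fields) + "\n")


def with_source(record: IndelRecord, source: Source) -> IndelRecord:
    return replace(record, source=source)
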