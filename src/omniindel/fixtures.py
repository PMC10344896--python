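"""Synthetic genomes, VCFs and genotype panels with machine-readable truth.

Every downstream stage is testable against planted ground truth: the
generator writes a genome with planted SSR arrays and (optionally)
duplicated 30-mers, a VCF with planted InDels of every size class and type
at controlled allele frequencies and missing rates, Multi-InDel clusters
with both collision-free and colliding haplotype-length sets, SyRI-style
structural-variant tables, and clustered genotype panels for the germplasm
stage.  All randomness flows from a single integer seed; outputs are
byte-reproducible.

Allele frequencies and missing rates are planted by exact count (the
requested frequency is realized up to rounding on the non-missing calls;
only the arrangement across samples is randomized) so that threshold
verdicts in the truth table are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import ssr as ssr_mod
from .germplasm import GenotypeMatrix
from .perfect import reverse_complement
from .variants import (
    GenotypeCall,
    IndelRecord,
    Source,
    normalize_indel,
    write_vcf,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class PlantedSsr:
    motif: str
    repeat_count: int
    pos: int


@dataclass(frozen=True)
class PlantedIndel:
    """One planted variant site.

    ``deltas`` holds one signed length change per alt allele (two or more
    entries make the site multi-allelic).  ``dup_flanks`` requests that both
    30-bp flanks be copied elsewhere in the genome (optionally as reverse
    complements) so the site fails the single-copy-flank screen.
    ``ssr_array`` ties the site to a planted SSR: the change is ``n_motifs``
    whole copies of that array's motif at the array start.
    """

    pos: int
    deltas: tuple[int, ...]
    target_maf: float = 0.3
    target_missing: float = 0.0
    ssr_array: int | None = None     # index into planted_ssrs
    n_motifs: int = 0                # whole motif copies for SSR-tied sites
    ssr_offset_bp: int = 0           # extra non-motif shift (breaks consistency)
    dup_flanks: bool = False
    dup_revcomp: bool = False
    label: str = ""


@dataclass(frozen=True)
class PlantedCluster:
    positions: tuple[int, ...]
    deltas: tuple[int, ...]
    expect_distinct: bool = True
    target_maf: float = 0.3
    target_missing: float = 0.0
    label: str = ""


@dataclass(frozen=True)
class PlantedSv:
    """A SyRI-table row: large/huge insertion or deletion, or a decoy."""

    vtype: str  # INS, DEL or a decoy class like INV/SYN/DUP/SNP
    length: int
    pos: int


@dataclass
class FixtureSpec:
    genome_length: int = 100_000
    seed: int = 17
    chrom: str = "chr1"
    n_samples: int = 200
    planted_ssrs: list[PlantedSsr] = field(default_factory=list)
    planted_indels: list[PlantedIndel] = field(default_factory=list)
    planted_multi_clusters: list[PlantedCluster] = field(default_factory=list)
    planted_svs: list[PlantedSv] = field(default_factory=list)


class FixtureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genome


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _break_accidental_ssrs(seq: np.ndarray, rng: np.random.Generator) -> None:
    """Mutate bases until the background contains no threshold-level SSR."""
    for _ in range(10):
        loci = ssr_mod.scan_ssrs(seq.tobytes().decode())
        if not loci:
            return
        for loc in loci:
            mid = (loc.start + loc.end) // 2
            cur = seq[mid]
            options = [b for b in _BASES if b != cur]
            seq[mid] = options[int(rng.integers(0, len(options)))]
    raise FixtureError("could not clear accidental SSRs from background")


def _pick_base(rng: np.random.Generator, *avoid: bytes) -> bytes:
    options = [b for b in _BASES if b not in avoid]
    return options[int(rng.integers(0, len(options)))]


def make_genome(spec: FixtureSpec) -> tuple[dict[str, str], pd.DataFrame]:
    """Build the fixture genome and the SSR truth table.

    Planted SSR arrays are made maximal by forcing the flanking bases to
    break the periodicity, so a scanner reports exactly the planted
    (start, motif, count).  Overlapping plants raise FixtureError.
    """
    rng = np.random.default_rng(spec.seed)
    seq = _random_bases(rng, spec.genome_length)
    _break_accidental_ssrs(seq, rng)

    intervals: list[tuple[int, int]] = []

    def claim(start: int, end: int, what: str) -> None:
        if start < 0 or end > spec.genome_length:
            raise FixtureError(f"{what} at [{start},{end}) outside genome")
        for s, e in intervals:
            if start < e and end > s:
                raise FixtureError(f"overlapping plants at [{start},{end})")
        intervals.append((start, end))

    truth_rows = []
    for ps in spec.planted_ssrs:
        motif = ps.motif.upper()
        p = len(motif)
        end = ps.pos + p * ps.repeat_count
        claim(ps.pos - 1, end + 1, f"SSR {motif}")
        arr = np.frombuffer((motif * ps.repeat_count).encode(), dtype="S1")
        seq[ps.pos : end] = arr
        # break periodicity at both boundaries so the run is exactly maximal
        seq[ps.pos - 1] = _pick_base(rng, motif[-1].encode())
        seq[end] = _pick_base(rng, motif[0].encode())
        truth_rows.append(
            {
                "chrom": spec.chrom,
                "start": ps.pos,
                "end": end,
                "motif": ssr_mod.canonical_motif(motif),
                "repeat_count": ps.repeat_count,
            }
        )

    genome = {spec.chrom: seq.tobytes().decode()}
    return genome, pd.DataFrame(
        truth_rows, columns=["chrom", "start", "end", "motif", "repeat_count"]
    )


def _apply_flank_duplications(
    genome: dict[str, str],
    spec: FixtureSpec,
    rng: np.random.Generator,
    site: PlantedIndel,
    affected: tuple[int, int],
    dest_cursor: list[int],
) -> dict[str, str]:
    """Copy both 30-bp flanks of a site to spare genome locations."""
    chrom = spec.chrom
    seq = list(genome[chrom])
    a0, a1 = affected
    for flank_seq in (genome[chrom][a0 - 30 : a0], genome[chrom][a1 : a1 + 30]):
        payload = (
            reverse_complement(flank_seq) if site.dup_revcomp else flank_seq
        )
        dest = dest_cursor[0]
        if dest + 30 > len(seq):
            raise FixtureError("no room for duplicated flank")
        seq[dest : dest + 30] = list(payload)
        dest_cursor[0] = dest + 60
    genome[chrom] = "".join(seq)
    return genome


# ---------------------------------------------------------------------------
# genotypes


def _plant_genotypes(
    rng: np.random.Generator,
    n_samples: int,
    alt_freqs: Sequence[float],
    missing_rate: float,
    sample_ids: Sequence[str],
) -> list[GenotypeCall]:
    """Genotypes with exact-count allele frequencies, random arrangement.

    Allele counts are fixed at round(freq * 2n') over the n' non-missing
    samples and dealt out by random permutation (a Hardy-Weinberg draw
    conditioned on the allele counts).
    """
    n_missing = int(round(missing_rate * n_samples))
    n_called = n_samples - n_missing
    pool: list[int] = []
    for ai, f in enumerate(alt_freqs, start=1):
        pool.extend([ai] * int(round(f * 2 * n_called)))
    if len(pool) > 2 * n_called:
        raise FixtureError("allele frequencies exceed 1")
    pool.extend([0] * (2 * n_called - len(pool)))
    pool_arr = np.array(pool)
    rng.shuffle(pool_arr)
    genotypes = [
        tuple(sorted((int(pool_arr[2 * i]), int(pool_arr[2 * i + 1]))))
        for i in range(n_called)
    ]
    missing_idx = set(
        rng.choice(n_samples, size=n_missing, replace=False).tolist()
    )
    calls: list[GenotypeCall] = []
    gi = 0
    for si in range(n_samples):
        if si in missing_idx:
            calls.append(GenotypeCall(sample_ids[si], (None, None)))
        else:
            calls.append(GenotypeCall(sample_ids[si], genotypes[gi]))
            gi += 1
    return calls


# ---------------------------------------------------------------------------
# variants


def _expected_verdict(site: PlantedIndel, len_range=(3, 10),
                      maf_min=0.05) -> str:
    max_abs = max(abs(d) for d in site.deltas)
    if not (len_range[0] <= max_abs <= len_range[1]):
        return "length"
    if len(site.deltas) > 1:
        return "dimorphic"
    if site.dup_flanks:
        return "flank"
    if site.target_maf < maf_min:
        return "maf"
    return "pass"


def _expected_ssr_class(site: PlantedIndel) -> str:
    if site.ssr_array is None:
        return "NON_SSR"
    if site.n_motifs > 0 and site.ssr_offset_bp == 0:
        return "SSR_MOTIF_CONSISTENT"
    return "SSR_OVERLAP"


def _build_indel_record(
    spec: FixtureSpec,
    genome: Mapping[str, str],
    rng: np.random.Generator,
    site: PlantedIndel,
) -> IndelRecord:
    chrom = spec.chrom
    seq = genome[chrom]
    if site.ssr_array is not None:
        arr = spec.planted_ssrs[site.ssr_array]
        motif = arr.motif.upper()
        pos = arr.pos - 1  # anchor immediately before the array
        delta = site.deltas[0]
        if delta < 0:
            ref = seq[pos : pos + 1 - delta]
            alt = seq[pos]
        else:
            ref = seq[pos]
            payload = (motif * ((delta // len(motif)) + 2))[:delta]
            if site.ssr_offset_bp:
                payload = _mutate_string(payload, rng)
            alt = ref + payload
        return IndelRecord.from_alleles(chrom, pos, ref, [alt])
    pos = site.pos
    ref_anchor = seq[pos]
    alts = []
    max_del = max((-d for d in site.deltas if d < 0), default=0)
    ref = seq[pos : pos + 1 + max_del]
    for d in site.deltas:
        if d < 0:
            alts.append(seq[pos : pos + 1 + max_del + d])
        else:
            ins = "".join(
                chr(b[0]) for b in _random_bases(rng, d)
            )
            alts.append(ref_anchor + ins + ref[1:])
    return IndelRecord.from_alleles(chrom, pos, ref, alts)


def _mutate_string(s: str, rng: np.random.Generator) -> str:
    i = len(s) // 2
    repl = chr(_pick_base(rng, s[i].encode())[0])
    return s[:i] + repl + s[i + 1 :]


def make_vcf(
    spec: FixtureSpec, genome: dict[str, str]
) -> tuple[list[IndelRecord], list[list[GenotypeCall]], pd.DataFrame]:
    """Plant all single-site InDels plus Multi-InDel clusters.

    Returns normalized records, per-record genotype calls, and a truth table
    with the expected size class, type, SSR class, Perfect verdict and
    Multi-InDel membership of every planted site.  Duplicated-flank plants
    mutate the genome in place (the copies must exist in the FASTA).
    """
    rng = np.random.default_rng(spec.seed + 1)
    sample_ids = [f"S{i:04d}" for i in range(spec.n_samples)]
    records: list[IndelRecord] = []
    calls: list[list[GenotypeCall]] = []
    truth_rows = []
    dest_cursor = [spec.genome_length - 2_000]

    for site in spec.planted_indels:
        if site.target_maf > 0.5:
            raise FixtureError(
                f"target_maf {site.target_maf} > 0.5 is not a minor frequency"
            )
        rec = _build_indel_record(spec, genome, rng, site)
        rec = normalize_indel(rec, genome)
        if site.dup_flanks:
            _apply_flank_duplications(
                genome, spec, rng, site, rec.affected_interval, dest_cursor
            )
        n_alts = len(rec.alt_alleles)
        freqs = [site.target_maf] * n_alts if n_alts == 1 else (
            [site.target_maf] + [0.05] * (n_alts - 1)
        )
        site_calls = _plant_genotypes(
            rng, spec.n_samples, freqs, site.target_missing, sample_ids
        )
        records.append(rec)
        calls.append(site_calls)
        truth_rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos + 1,
                "label": site.label,
                "size_class": rec.size_class.value,
                "variant_type": rec.variant_type.value,
                "target_maf": site.target_maf,
                "target_missing": site.target_missing,
                "ssr_class": _expected_ssr_class(site),
                "perfect_verdict": _expected_verdict(site),
                "multi_id": "",
                "expect_distinct": "",
                "expect_in_final": "",
            }
        )

    cluster_records, cluster_calls, cluster_truth = make_multi_cluster(
        spec, genome
    )
    records.extend(cluster_records)
    calls.extend(cluster_calls)
    frames = [
        f for f in (pd.DataFrame(truth_rows, columns=_TRUTH_COLUMNS),
                    cluster_truth)
        if not f.empty
    ]
    truth = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=_TRUTH_COLUMNS))
    order = np.argsort([r.pos for r in records], kind="stable")
    records = [records[i] for i in order]
    calls = [calls[i] for i in order]
    truth = truth.sort_values("pos", kind="stable").reset_index(drop=True)
    return records, calls, truth


_TRUTH_COLUMNS = [
    "chrom", "pos", "label", "size_class", "variant_type", "target_maf",
    "target_missing", "ssr_class", "perfect_verdict", "multi_id",
    "expect_distinct", "expect_in_final",
]


def make_multi_cluster(
    spec: FixtureSpec, genome: dict[str, str]
) -> tuple[list[IndelRecord], list[list[GenotypeCall]], pd.DataFrame]:
    """Plant Multi-InDel clusters with declared subset-sum behaviour.

    Clusters marked ``expect_distinct`` use collision-free delta sets;
    colliding sets are planted as declared.  The truth table records the
    expected acceptance of each cluster (before the spacing filter, which
    is evaluated across clusters by the caller's layout).
    """
    from .multiindel import distinct_subset_sums_bruteforce

    rng = np.random.default_rng(spec.seed + 2)
    sample_ids = [f"S{i:04d}" for i in range(spec.n_samples)]
    records: list[IndelRecord] = []
    calls: list[list[GenotypeCall]] = []
    truth_rows = []
    spans: list[tuple[str, int, int, bool]] = []
    for ci, cluster in enumerate(spec.planted_multi_clusters):
        if len(cluster.positions) != len(cluster.deltas):
            raise FixtureError("cluster positions and deltas differ in length")
        if cluster.target_maf > 0.5:
            raise FixtureError("cluster target_maf > 0.5")
        distinct = distinct_subset_sums_bruteforce(list(cluster.deltas))
        if distinct != cluster.expect_distinct:
            raise FixtureError(
                f"cluster {ci}: declared expect_distinct={cluster.expect_distinct} "
                f"but deltas enumerate to {distinct}"
            )
        member_recs = []
        for pos, delta in zip(cluster.positions, cluster.deltas):
            site = PlantedIndel(pos=pos, deltas=(delta,),
                                target_maf=cluster.target_maf,
                                target_missing=cluster.target_missing)
            rec = _build_indel_record(spec, genome, rng, site)
            rec = normalize_indel(rec, genome)
            member_recs.append(rec)
            calls.append(
                _plant_genotypes(rng, spec.n_samples, [cluster.target_maf],
                                 cluster.target_missing, sample_ids)
            )
        records.extend(member_recs)
        cid = cluster.label or f"M{ci}"
        spans.append(
            (spec.chrom, member_recs[0].affected_start,
             member_recs[-1].affected_end, distinct)
        )
        for rec in member_recs:
            truth_rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos + 1,
                    "label": cid,
                    "size_class": rec.size_class.value,
                    "variant_type": rec.variant_type.value,
                    "target_maf": cluster.target_maf,
                    "target_missing": cluster.target_missing,
                    "ssr_class": "NON_SSR",
                    "perfect_verdict": "pass"
                    if cluster.target_maf >= 0.05 else "maf",
                    "multi_id": cid,
                    "expect_distinct": distinct,
                    "expect_in_final": "",
                }
            )
    # spacing across accepted clusters decides final-panel membership
    accepted = [s for s in spans if s[3]]
    accepted.sort(key=lambda s: s[1])
    removed = set()
    for a, b in zip(accepted, accepted[1:]):
        if b[1] - a[2] <= 200:
            removed.add(a[1])
            removed.add(b[1])
    truth = pd.DataFrame(truth_rows, columns=_TRUTH_COLUMNS)
    span_by_id = {
        (cluster.label or f"M{ci}"): spans[ci]
        for ci, cluster in enumerate(spec.planted_multi_clusters)
    }
    truth["expect_in_final"] = [
        bool(span_by_id[mid][3]) and span_by_id[mid][1] not in removed
        if mid else ""
        for mid in truth["multi_id"]
    ]
    return records, calls, truth


# ---------------------------------------------------------------------------
# SyRI-style tables


def make_syri_table(spec: FixtureSpec) -> tuple[str, pd.DataFrame]:
    """SyRI-style TSV text for planted large variants plus decoy rows."""
    lines = []
    truth_rows = []
    qchrom = spec.chrom.replace("chr", "qry")
    for i, sv in enumerate(spec.planted_svs):
        start = sv.pos
        if sv.vtype == "DEL":
            end = start + sv.length - 1
            qs, qe = start, start
        elif sv.vtype == "INS":
            end = start
            qs, qe = start, start + sv.length - 1
        else:  # decoy classes span reference sequence
            end = start + sv.length - 1
            qs, qe = start, end
        lines.append(
            "\t".join(
                [
                    spec.chrom, str(start), str(end), "-", "-",
                    qchrom, str(qs), str(qe),
                    f"{sv.vtype}{i}", "-", sv.vtype, "-",
                ]
            )
        )
        if sv.vtype in ("INS", "DEL"):
            from .variants import classify_size

            truth_rows.append(
                {
                    "chrom": spec.chrom,
                    "pos": start,
                    "vtype": sv.vtype,
                    "length": sv.length,
                    "size_class": classify_size(sv.length).value,
                }
            )
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "pos", "vtype", "length", "size_class"]
    )
    return "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------------------
# germplasm panels


def make_cluster_panel(
    n_clusters: int = 3,
    n_per_cluster: int = 30,
    n_signature_loci: int = 20,
    n_shared_loci: int = 20,
    missing_rate: float = 0.02,
    seed: int = 0,
) -> tuple[GenotypeMatrix, list[int]]:
    """Genotype panel of well-separated clusters with planted labels.

    Each cluster is homozygous alt (dosage 2) at its private signature loci
    and reference elsewhere; shared loci segregate at a common frequency in
    all clusters.  Separation is deterministic; only the shared loci and
    missingness are random.
    """
    rng = np.random.default_rng(seed)
    n_samples = n_clusters * n_per_cluster
    n_loci = n_clusters * n_signature_loci + n_shared_loci
    codes = np.zeros((n_samples, n_loci))
    labels = []
    for c in range(n_clusters):
        rows = slice(c * n_per_cluster, (c + 1) * n_per_cluster)
        cols = slice(c * n_signature_loci, (c + 1) * n_signature_loci)
        codes[rows, cols] = 2.0
        labels.extend([c] * n_per_cluster)
    shared = rng.binomial(2, 0.3, size=(n_samples, n_shared_loci)).astype(float)
    codes[:, n_clusters * n_signature_loci :] = shared
    miss = rng.random(codes.shape) < missing_rate
    codes[miss] = np.nan
    # no underscores: bare newick labels map "_" to space on re-parse
    sample_ids = [f"G{c}x{i:03d}" for c, i in
                  zip(labels, range(n_samples))]
    locus_ids = [f"L{j:03d}" for j in range(n_loci)]
    return GenotypeMatrix(sample_ids, locus_ids, codes), labels


# ---------------------------------------------------------------------------
# the default end-to-end fixture


def default_fixture_spec(seed: int = 17, n_samples: int = 200) -> FixtureSpec:
    """The standard study conditions: a 100-kb genome, 200 samples, planted
    SSRs of every motif length, InDels of every class/type/verdict, and five
    Multi-InDel clusters exercising distinctness and spacing."""
    ssrs = [
        PlantedSsr("A", 12, 2_000),
        PlantedSsr("AT", 8, 4_000),
        PlantedSsr("ACG", 6, 6_000),
        PlantedSsr("AGAT", 5, 8_000),
        PlantedSsr("AACGT", 4, 10_000),
        PlantedSsr("ACGTAC", 4, 12_000),
        PlantedSsr("CT", 9, 14_000),
        PlantedSsr("GAA", 7, 16_000),
    ]
    indels: list[PlantedIndel] = []
    cursor = 20_000

    def put(**kw) -> None:
        nonlocal cursor
        indels.append(PlantedIndel(pos=cursor, **kw))
        cursor += 400

    # size classes and types
    put(deltas=(1,), label="soi_ins1")
    put(deltas=(-2,), label="soi_del2")
    put(deltas=(3,), label="moi_ins3")
    put(deltas=(-4,), label="moi_del4")
    put(deltas=(5,), label="moi_ins5")
    put(deltas=(-6,), label="moi_del6")
    put(deltas=(7,), label="moi_ins7")
    put(deltas=(-8,), label="moi_del8")
    put(deltas=(9,), label="moi_ins9")
    put(deltas=(-10,), label="moi_del10")
    put(deltas=(11,), label="moi_ins11_lenfail")
    put(deltas=(-20,), label="moi_del20_lenfail")
    put(deltas=(49,), label="moi_ins49_lenfail")
    # mixed and multi-allelic
    put(deltas=(-2, 1), label="mixed_small")
    put(deltas=(-5, 4), label="mixed_medium")
    put(deltas=(-3, -5), label="multiallelic_del")
    # frequency / missingness edge plants
    put(deltas=(4,), target_maf=0.04, label="maf_fail")
    put(deltas=(5,), target_maf=0.05, label="maf_boundary_pass")
    put(deltas=(6,), target_maf=0.10, label="maf_at_multi_threshold")
    put(deltas=(-7,), target_missing=0.50, label="missing_at_threshold")
    put(deltas=(8,), target_missing=0.05, label="missing_5pct")
    # flank-uniqueness failures
    put(deltas=(-5,), dup_flanks=True, label="dup_flanks")
    put(deltas=(6,), dup_flanks=True, dup_revcomp=True, label="dup_flanks_rc")
    # SSR-tied sites
    indels.append(PlantedIndel(pos=0, deltas=(-4,), ssr_array=1, n_motifs=2,
                               label="ssr_consistent_del"))
    indels.append(PlantedIndel(pos=0, deltas=(6,), ssr_array=2, n_motifs=2,
                               label="ssr_consistent_ins"))
    indels.append(PlantedIndel(pos=0, deltas=(-3,), ssr_array=6, n_motifs=0,
                               ssr_offset_bp=1, label="ssr_overlap_only"))
    indels.append(PlantedIndel(pos=0, deltas=(5,), ssr_array=7, n_motifs=0,
                               ssr_offset_bp=1, label="ssr_overlap_ins"))
    # additional isolated pass sites
    for i in range(12):
        put(deltas=((3 + i % 8) * (1 if i % 2 else -1),),
            label=f"pass_extra_{i}")

    clusters = [
        PlantedCluster(positions=(40_000, 40_060, 40_120), deltas=(3, 5, 9),
                       expect_distinct=True, label="c_distinct"),
        PlantedCluster(positions=(42_000, 42_060, 42_120), deltas=(3, 4, 7),
                       expect_distinct=False, label="c_colliding"),
        PlantedCluster(positions=(44_000, 44_050, 44_100), deltas=(-3, 5, 9),
                       expect_distinct=True, label="c_close_a"),
        PlantedCluster(positions=(44_260, 44_310, 44_360), deltas=(4, 7, 9),
                       expect_distinct=True, label="c_close_b"),
        PlantedCluster(positions=(47_000, 47_050, 47_100, 47_150),
                       deltas=(3, 5, 10, -9), expect_distinct=True,
                       label="c_distinct_k4"),
    ]
    svs = [
        PlantedSv("DEL", 300, 1_000),
        PlantedSv("INS", 1_200_000, 5_000),
        PlantedSv("DEL", 75, 9_000),
        PlantedSv("INS", 52, 13_000),
        PlantedSv("DEL", 2_500, 17_000),
        PlantedSv("INV", 5_000, 21_000),
        PlantedSv("SYN", 10_000, 30_000),
        PlantedSv("DUP", 800, 45_000),
        PlantedSv("SNP", 1, 50_000),
    ]
    return FixtureSpec(
        genome_length=100_000,
        seed=seed,
        n_samples=n_samples,
        planted_ssrs=ssrs,
        planted_indels=indels,
        planted_multi_clusters=clusters,
        planted_svs=svs,
    )


def generate(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA, VCF, SyRI table and truth TSVs; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, ssr_truth = make_genome(spec)
    records, calls, truth = make_vcf(spec, genome)
    paths = {
        "genome": out / "genome.fa",
        "vcf": out / "variants.vcf",
        "syri": out / "syri.tsv",
        "truth": out / "truth.tsv",
        "ssr_truth": out / "ssr_truth.tsv",
        "syri_truth": out / "syri_truth.tsv",
    }
    with open(paths["genome"], "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    write_vcf(records, calls, {c: len(s) for c, s in genome.items()},
              paths["vcf"])
    syri_text, syri_truth = make_syri_table(spec)
    paths["syri"].write_text(syri_text)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    ssr_truth.to_csv(paths["ssr_truth"], sep="\t", index=False)
    syri_truth.to_csv(paths["syri_truth"], sep="\t", index=False)
    return paths


def load_genome(path: str | Path) -> dict[str, str]:
    """Read a FASTA into an in-memory chrom -> sequence mapping."""
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
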