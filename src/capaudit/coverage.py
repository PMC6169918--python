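"""Per-sample depth over gene regions and coverage-sufficiency calls.

The audit asks, per sample and gene: after discarding duplicate reads and
those with mapping quality below 30, is the average depth over the gene's
canonical exons at least 25x — the depth at which a short-read somatic caller
retains near-full sensitivity for a clonal heterozygous mutation at typical
tumor purity? Genes are then classified at the cohort level:

* an *undercovered cohort* has more than 75% of samples below the 25x
  average (strict >);
* an *undercovered gene* has fewer than 80% of region bases whose
  cross-sample mean depth exceeds 20 (strict >); zero qualifying bases means
  capture probes are absent outright, a positive-but-<80% fraction means
  incomplete probe coverage.

All thresholds live in :class:`AuditThresholds` so boundary semantics are
stated once and logged with every report.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from capaudit.intervals import GeneModel, GenomeInterval, total_length

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AuditThresholds:
    """Every numeric rule of the audit, with its boundary semantics.

    min_mapq: reads strictly below this mapping quality are discarded.
    min_avg_depth: average region depth (x-fold) at or above this is
        sufficient (inclusive).
    cohort_insufficiency_frac: a cohort is undercovered when the insufficient
        fraction strictly exceeds this.
    base_depth_gt: a base qualifies when its cross-sample mean depth strictly
        exceeds this.
    qualifying_frac: gene/exon is covered when the qualifying-base fraction is
        at least this (inclusive).
    """

    min_mapq: int = 30
    min_avg_depth: float = 25.0
    cohort_insufficiency_frac: float = 0.75
    base_depth_gt: float = 20.0
    qualifying_frac: float = 0.80

    def __post_init__(self) -> None:
        if self.min_mapq < 0 or self.min_avg_depth <= 0 or self.base_depth_gt <= 0:
            raise ValueError("depth/MAPQ thresholds must be positive")
        for name in ("cohort_insufficiency_frac", "qualifying_frac"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")

    def describe(self) -> str:
        return (
            f"min_mapq={self.min_mapq} min_avg_depth={self.min_avg_depth} "
            f"cohort_insufficiency_frac>{self.cohort_insufficiency_frac} "
            f"base_depth>{self.base_depth_gt} qualifying_frac>={self.qualifying_frac}"
        )


DEFAULT_THRESHOLDS = AuditThresholds()


@dataclass
class DepthTrack:
    """Per-base depth over a gene's region bases, in chromosomal order."""

    gene_symbol: str
    region_mode: str
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if self.depths.ndim != 1 or self.depths.size == 0:
            raise ValueError(f"{self.gene_symbol}: depth track must be non-empty 1-d")
        if np.any(self.depths < 0):
            raise ValueError(f"{self.gene_symbol}: negative depth")

    def __len__(self) -> int:
        return int(self.depths.size)


@dataclass(frozen=True)
class SampleCoverage:
    """One sample's filtered read count and average region coverage for a gene."""

    sample_id: str
    gene_symbol: str
    read_count: int
    avg_exon_coverage: float
    sufficient: bool
    cohort_id: str = ""
    kit_name: str = ""


@dataclass(frozen=True)
class UndercoverageCall:
    """Depth-based gene status: covered / undercovered (incomplete or absent)."""

    gene_symbol: str
    qualifying_fraction: float
    status: str
    exon_flags: tuple[bool, ...] = ()

    @property
    def all_exons_undercovered(self) -> bool:
        return bool(self.exon_flags) and all(self.exon_flags)


# ---------------------------------------------------------------------------
# Alignment filtering and depth computation


def filter_alignments(records: Iterable, thresholds: AuditThresholds = DEFAULT_THRESHOLDS):
    """Yield alignments surviving the audit's read filters.

    Drops unmapped, duplicate-flagged, secondary and supplementary records and
    any with MAPQ strictly below ``thresholds.min_mapq`` (MAPQ == min_mapq is
    kept). A mapped record without a CIGAR is malformed and raises.
    """
    for rec in records:
        if rec.is_unmapped or rec.is_duplicate or rec.is_secondary or rec.is_supplementary:
            continue
        if rec.mapping_quality < thresholds.min_mapq:
            continue
        if rec.cigartuples is None:
            raise ValueError(f"mapped read {rec.query_name!r} has no CIGAR")
        yield rec


# CIGAR ops that consume the reference and represent aligned bases (M, =, X).
_ALIGNED_OPS = frozenset({0, 7, 8})
# Ops that consume the reference without aligned bases (D, N).
_REF_SKIP_OPS = frozenset({2, 3})


def _aligned_blocks(rec) -> list[tuple[int, int]]:
    """Reference-consuming aligned segments of a read, excluding deletions/skips."""
    blocks: list[tuple[int, int]] = []
    pos = rec.reference_start
    for op, length in rec.cigartuples:
        if op in _ALIGNED_OPS:
            blocks.append((pos, pos + length))
            pos += length
        elif op in _REF_SKIP_OPS:
            pos += length
    return blocks


class RegionIndex:
    """Maps genomic coordinates of a gene region to concatenated track offsets."""

    def __init__(self, gene: GeneModel, region_mode: str):
        self.gene = gene
        self.region_mode = region_mode
        self.intervals = gene.region(region_mode)
        if not self.intervals:
            raise ValueError(
                f"{gene.gene_symbol}: empty region in mode {region_mode!r}"
            )
        self.length = total_length(self.intervals)
        offsets = []
        off = 0
        for iv in self.intervals:
            offsets.append(off)
            off += len(iv)
        self._offsets = offsets

    def exon_slices(self) -> list[slice]:
        """Track slice per region interval, in chromosomal order."""
        return [
            slice(off, off + len(iv))
            for off, iv in zip(self._offsets, self.intervals)
        ]

    def project(self, start: int, end: int) -> list[tuple[int, int]]:
        """Track-offset spans covered by the genomic span [start, end)."""
        spans = []
        for off, iv in zip(self._offsets, self.intervals):
            lo, hi = max(start, iv.start), min(end, iv.end)
            if lo < hi:
                spans.append((off + lo - iv.start, off + hi - iv.start))
        return spans

    def locus_slice(self, locus: GenomeInterval) -> list[tuple[int, int]]:
        if locus.chrom != self.gene.chrom:
            raise ValueError(
                f"locus {locus.chrom}:{locus.start}-{locus.end} not on "
                f"{self.gene.gene_symbol}'s chromosome"
            )
        spans = self.project(locus.start, locus.end)
        if sum(hi - lo for lo, hi in spans) != len(locus):
            raise ValueError(
                f"locus {locus.chrom}:{locus.start}-{locus.end} extends outside "
                f"the {self.region_mode} region of {self.gene.gene_symbol}"
            )
        return spans


def depth_track(
    records: Iterable,
    gene: GeneModel,
    region_mode: str = "exon",
    prefiltered: bool = True,
    thresholds: AuditThresholds = DEFAULT_THRESHOLDS,
) -> DepthTrack:
    """Per-base depth over the gene's region from alignment records.

    Depth at a base counts records whose reference-consuming aligned segments
    (CIGAR M/=/X) cover it; deletions and skips contribute nothing. Records
    should already be filtered (``prefiltered=False`` applies
    :func:`filter_alignments` first). Overlapping mate pairs double count.
    """
    index = RegionIndex(gene, region_mode)
    if not prefiltered:
        records = filter_alignments(records, thresholds)
    diff = np.zeros(index.length + 1, dtype=np.int64)
    for rec in records:
        if rec.reference_name != gene.chrom:
            continue
        for bstart, bend in _aligned_blocks(rec):
            for lo, hi in index.project(bstart, bend):
                diff[lo] += 1
                diff[hi] -= 1
    depths = np.cumsum(diff[:-1])
    return DepthTrack(gene.gene_symbol, region_mode, depths)


def count_region_reads(records: Iterable, gene: GeneModel, region_mode: str = "exon") -> int:
    """Number of (filtered) records with >=1 aligned base in the gene region."""
    index = RegionIndex(gene, region_mode)
    n = 0
    for rec in records:
        if rec.reference_name != gene.chrom:
            continue
        if any(index.project(bs, be) for bs, be in _aligned_blocks(rec)):
            n += 1
    return n


# ---------------------------------------------------------------------------
# Sufficiency and undercoverage calls


def average_exon_coverage(track: DepthTrack) -> float:
    """Arithmetic mean depth over the track's region bases."""
    return float(np.mean(track.depths))


def is_sufficient(avg: float, thresholds: AuditThresholds = DEFAULT_THRESHOLDS) -> bool:
    """Sufficient iff average depth meets the minimum threshold (inclusive)."""
    if avg < 0:
        raise ValueError("average depth must be non-negative")
    return avg >= thresholds.min_avg_depth


def undercovered_cohort(
    sufficiency_flags: Sequence[bool],
    thresholds: AuditThresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """True iff the insufficient fraction strictly exceeds the cohort threshold."""
    if len(sufficiency_flags) == 0:
        raise ValueError("cohort has no samples")
    n_insufficient = sum(1 for f in sufficiency_flags if not f)
    return n_insufficient / len(sufficiency_flags) > thresholds.cohort_insufficiency_frac


def mean_depth_profile(tracks: Sequence[DepthTrack]) -> np.ndarray:
    """Elementwise mean depth across samples (plain arithmetic mean)."""
    if not tracks:
        raise ValueError("mean_depth_profile requires at least one track")
    first = tracks[0]
    for t in tracks[1:]:
        if (t.gene_symbol, t.region_mode, len(t)) != (
            first.gene_symbol,
            first.region_mode,
            len(first),
        ):
            raise ValueError("tracks must share gene, region mode and length")
    return np.mean(np.stack([t.depths for t in tracks]), axis=0)


def _qualifying_fraction(profile: np.ndarray, thresholds: AuditThresholds) -> float:
    profile = np.asarray(profile)
    if profile.size == 0:
        raise ValueError("empty depth profile")
    return float(np.mean(profile > thresholds.base_depth_gt))


def _status_from_fraction(fraction: float, thresholds: AuditThresholds) -> str:
    if fraction >= thresholds.qualifying_frac:
        return "covered"
    return "undercovered_absent" if fraction == 0 else "undercovered_incomplete"


def call_undercovered_gene(
    profile: np.ndarray,
    gene_symbol: str = "",
    thresholds: AuditThresholds = DEFAULT_THRESHOLDS,
    exon_slices: Sequence[slice] | None = None,
) -> UndercoverageCall:
    """Classify a gene from its cross-sample mean-depth profile.

    The qualifying fraction is the share of bases with mean depth strictly
    above ``base_depth_gt``; at least ``qualifying_frac`` of bases must
    qualify for the gene to be covered. Zero qualifying bases is called
    absent probe coverage, anything between zero and the threshold
    incomplete. When ``exon_slices`` is given, each exon is flagged by the
    same rule.
    """
    profile = np.asarray(profile, dtype=float)
    fraction = _qualifying_fraction(profile, thresholds)
    status = _status_from_fraction(fraction, thresholds)
    exon_flags: tuple[bool, ...] = ()
    if exon_slices is not None:
        exon_flags, _ = call_undercovered_exons(
            [profile[s] for s in exon_slices], thresholds
        )
    return UndercoverageCall(gene_symbol, fraction, status, exon_flags)


def call_undercovered_exons(
    exon_profiles: Sequence[np.ndarray],
    thresholds: AuditThresholds = DEFAULT_THRESHOLDS,
) -> tuple[tuple[bool, ...], bool]:
    """Flag each exon whose qualifying-base fraction falls below threshold.

    Returns (per-exon undercovered flags, all_exons_undercovered).
    """
    if not exon_profiles:
        raise ValueError("no exon profiles supplied")
    flags = tuple(
        _qualifying_fraction(np.asarray(p, dtype=float), thresholds)
        < thresholds.qualifying_frac
        for p in exon_profiles
    )
    return flags, all(flags)


def mean_depth_in_loci(
    track: DepthTrack,
    gene: GeneModel,
    loci: Sequence[GenomeInterval],
) -> list[float]:
    """Mean depth over each locus's bases (e.g. MSI repeat positions).

    A locus outside the gene's region raises, naming the locus.
    """
    index = RegionIndex(gene, track.region_mode)
    if index.length != len(track):
        raise ValueError(f"{gene.gene_symbol}: track length does not match region")
    means = []
    for locus in loci:
        spans = index.locus_slice(locus)
        vals = np.concatenate([track.depths[lo:hi] for lo, hi in spans])
        means.append(float(np.mean(vals)))
    return means


# ---------------------------------------------------------------------------
# I/O: depth TSV (samtools-depth style) and per-sample coverage tables


def read_depth_tsv(
    path: str | Path,
    genes: Sequence[GeneModel],
    region_mode: str = "exon",
    sample_ids: Sequence[str] | None = None,
) -> dict[str, dict[str, DepthTrack]]:
    """Read a samtools-depth-style TSV into per-sample, per-gene depth tracks.

    Layout: chrom, 1-based position, then one depth column per sample. A
    ``#chrom`` header naming the samples is honoured; otherwise samples are
    named S1..Sn or taken from ``sample_ids``. Positions absent from the file
    get depth 0; positions outside every gene region are skipped with a
    warning; a duplicated (chrom, pos) row raises.
    """
    path = Path(path)
    indexes = {g.gene_symbol: RegionIndex(g, region_mode) for g in genes}
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header_names: list[str] | None = None
    if lines and lines[0].startswith("#"):
        header_names = lines[0].lstrip("#").split("\t")[2:]
        lines = lines[1:]
    n_cols = len(lines[0].split("\t")) - 2 if lines else (
        len(sample_ids) if sample_ids else 1
    )
    if sample_ids is None:
        sample_ids = header_names or [f"S{i + 1}" for i in range(n_cols)]
    arrays = {
        sid: {g: np.zeros(ix.length, dtype=np.int64) for g, ix in indexes.items()}
        for sid in sample_ids
    }
    seen: set[tuple[str, int]] = set()
    n_skipped = 0
    for line in lines:
        fields = line.split("\t")
        chrom, pos1 = fields[0], int(fields[1])
        if (chrom, pos1) in seen:
            raise ValueError(f"{path}: duplicate depth row for {chrom}:{pos1}")
        seen.add((chrom, pos1))
        pos0 = pos1 - 1  # 1-based input -> internal 0-based
        hit = False
        for g, ix in indexes.items():
            if ix.gene.chrom != chrom:
                continue
            spans = ix.project(pos0, pos0 + 1)
            if spans:
                hit = True
                off = spans[0][0]
                for sid, depth_s in zip(sample_ids, fields[2:]):
                    arrays[sid][g][off] = int(depth_s)
        if not hit:
            n_skipped += 1
    if n_skipped:
        logger.warning("%s: %d positions outside all gene regions skipped", path, n_skipped)
    return {
        sid: {
            g: DepthTrack(g, region_mode, arr) for g, arr in per_gene.items()
        }
        for sid, per_gene in arrays.items()
    }


def write_depth_tsv(
    path: str | Path,
    genes: Sequence[GeneModel],
    tracks: Mapping[str, Mapping[str, DepthTrack]],
    region_mode: str = "exon",
) -> None:
    """Write per-sample tracks as a samtools-depth-style TSV with a sample header."""
    path = Path(path)
    sample_ids = sorted(tracks)
    with path.open("w") as fh:
        fh.write("#chrom\tpos\t" + "\t".join(sample_ids) + "\n")
        for gene in genes:
            index = RegionIndex(gene, region_mode)
            off = 0
            for iv in index.intervals:
                for k in range(len(iv)):
                    row = [
                        str(int(tracks[sid][gene.gene_symbol].depths[off + k]))
                        for sid in sample_ids
                    ]
                    fh.write(f"{gene.chrom}\t{iv.start + k + 1}\t" + "\t".join(row) + "\n")
                off += len(iv)


_COVERAGE_COLUMNS = (
    "sample_id",
    "cohort",
    "kit",
    "gene",
    "read_count",
    "avg_exon_coverage",
)


def write_coverage_tsv(
    rows: Sequence[SampleCoverage],
    path: str | Path,
    thresholds: AuditThresholds = DEFAULT_THRESHOLDS,
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# thresholds: {thresholds.describe()}\n")
        fh.write("\t".join(_COVERAGE_COLUMNS + ("sufficient",)) + "\n")
        for r in rows:
            fh.write(
                f"{r.sample_id}\t{r.cohort_id}\t{r.kit_name}\t{r.gene_symbol}\t"
                f"{r.read_count}\t{r.avg_exon_coverage:.6g}\t{int(r.sufficient)}\n"
            )


def read_coverage_tsv(
    path: str | Path,
    thresholds: AuditThresholds = DEFAULT_THRESHOLDS,
) -> list[SampleCoverage]:
    """Read a per-sample coverage TSV; sufficiency is recomputed from thresholds."""
    path = Path(path)
    rows: list[SampleCoverage] = []
    with path.open() as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                idx = {c: header.index(c) for c in _COVERAGE_COLUMNS}
                continue
            avg = float(fields[idx["avg_exon_coverage"]])
            rows.append(
                SampleCoverage(
                    sample_id=fields[idx["sample_id"]],
                    gene_symbol=fields[idx["gene"]],
                    read_count=int(fields[idx["read_count"]]),
                    avg_exon_coverage=avg,
                    sufficient=is_sufficient(avg, thresholds),
                    cohort_id=fields[idx["cohort"]],
                    kit_name=fields[idx["kit"]],
                )
            )
    return rows


def summarize_gene_coverage(
    rows: Sequence[SampleCoverage],
    read_count_below: int = 1000,
    thresholds: AuditThresholds = DEFAULT_THRESHOLDS,
) -> dict:
    """Cohort summary of one gene's per-sample coverage table.

    Reports the sample count, how many samples fall strictly below
    ``read_count_below`` filtered reads, the median filtered read count, the
    maximum average region coverage, and how many samples are sufficient at
    the audit threshold.
    """
    if not rows:
        raise ValueError("no coverage rows supplied")
    read_counts = [r.read_count for r in rows]
    return {
        "n_samples": len(rows),
        "n_below_read_count": sum(1 for c in read_counts if c < read_count_below),
        "median_read_count": float(statistics.median(read_counts)),
        "max_avg_coverage": max(r.avg_exon_coverage for r in rows),
        "n_sufficient": sum(
            1 for r in rows if is_sufficient(r.avg_exon_coverage, thresholds)
        ),
    }
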