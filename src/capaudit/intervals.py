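"""Genomic interval model and arithmetic.

Everything downstream — depth tracks, capture-design overlap, MSI-locus
means — reduces to base counting over half-open intervals. Coordinates are
uniformly 0-based half-open (BED convention); readers for 1-based dialects
convert on input. Touching intervals merge: adjacent capture probes are not
distinguished, and base-overlap arithmetic is unaffected by coalescing.
Strand is carried on gene models but ignored by all coverage math.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A half-open interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


def merge_intervals(intervals: Sequence[GenomeInterval]) -> list[GenomeInterval]:
    """Merge intervals on a single chromosome into a sorted disjoint list.

    Touching intervals (end == next start) are coalesced. Raises ``ValueError``
    if the intervals span more than one chromosome.
    """
    if not intervals:
        return []
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValueError(f"merge_intervals requires one chromosome, got {sorted(chroms)}")
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged: list[GenomeInterval] = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start <= last.end:  # overlap or touch
            if iv.end > last.end:
                merged[-1] = GenomeInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def _group_by_chrom(
    intervals: Iterable[GenomeInterval],
) -> dict[str, list[GenomeInterval]]:
    out: dict[str, list[GenomeInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def total_length(intervals: Iterable[GenomeInterval]) -> int:
    """Total base count of a disjoint interval collection."""
    return sum(len(iv) for iv in intervals)


def intersect_bases(
    a: Sequence[GenomeInterval], b: Sequence[GenomeInterval]
) -> int:
    """Number of bases shared between two interval collections.

    Symmetric; per-chromosome sweep over the merged forms of each side, so
    internally overlapping inputs do not double count.
    """
    by_a = _group_by_chrom(a)
    by_b = _group_by_chrom(b)
    shared = 0
    for chrom in by_a.keys() & by_b.keys():
        xs = merge_intervals(by_a[chrom])
        ys = merge_intervals(by_b[chrom])
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i].start, ys[j].start)
            hi = min(xs[i].end, ys[j].end)
            if lo < hi:
                shared += hi - lo
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return shared


def intersect_intervals(
    a: Sequence[GenomeInterval], b: Sequence[GenomeInterval]
) -> list[GenomeInterval]:
    """The interval set covering bases(a) ∩ bases(b), sorted per chromosome."""
    by_a = _group_by_chrom(a)
    by_b = _group_by_chrom(b)
    out: list[GenomeInterval] = []
    for chrom in sorted(by_a.keys() & by_b.keys()):
        xs = merge_intervals(by_a[chrom])
        ys = merge_intervals(by_b[chrom])
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i].start, ys[j].start)
            hi = min(xs[i].end, ys[j].end)
            if lo < hi:
                out.append(GenomeInterval(chrom, lo, hi))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return out


def _check_sorted_disjoint(intervals: Sequence[GenomeInterval], what: str) -> None:
    for prev, cur in zip(intervals, intervals[1:]):
        if cur.start < prev.end or cur.chrom != prev.chrom:
            raise ValueError(f"{what} intervals must be sorted and disjoint")


@dataclass(frozen=True)
class GeneModel:
    """A gene's canonical exon and CDS intervals on one chromosome.

    ``cds`` is the protein-coding subset of the exons (may be empty for
    non-coding genes). Exons are sorted and pairwise disjoint; every CDS base
    lies within an exon.
    """

    gene_symbol: str
    chrom: str
    strand: str
    exons: tuple[GenomeInterval, ...]
    cds: tuple[GenomeInterval, ...] = ()

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_symbol}: gene must have at least one exon")
        object.__setattr__(self, "exons", tuple(self.exons))
        object.__setattr__(self, "cds", tuple(self.cds))
        _check_sorted_disjoint(self.exons, f"{self.gene_symbol} exon")
        _check_sorted_disjoint(self.cds, f"{self.gene_symbol} CDS")
        for iv in self.exons + self.cds:
            if iv.chrom != self.chrom:
                raise ValueError(f"{self.gene_symbol}: interval on wrong chromosome")
        if self.cds and intersect_bases(self.cds, self.exons) != total_length(self.cds):
            raise ValueError(f"{self.gene_symbol}: CDS extends outside exons")

    @property
    def exon_length(self) -> int:
        return total_length(self.exons)

    @property
    def cds_length(self) -> int:
        return total_length(self.cds)

    def region(self, region_mode: str) -> tuple[GenomeInterval, ...]:
        """Exon or CDS intervals per ``region_mode`` ('exon' or 'cds')."""
        if region_mode == "exon":
            return self.exons
        if region_mode == "cds":
            return self.cds
        raise ValueError(f"region_mode must be 'exon' or 'cds', got {region_mode!r}")

    def region_length(self, region_mode: str) -> int:
        return total_length(self.region(region_mode))


@dataclass(frozen=True)
class CaptureDesign:
    """A capture kit's merged target intervals, keyed by chromosome."""

    kit_name: str
    targets: Mapping[str, tuple[GenomeInterval, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = {}
        for chrom, ivs in self.targets.items():
            ivs = tuple(ivs)
            # enforce the merged invariant (touching intervals coalesce too)
            for prev, cur in zip(ivs, ivs[1:]):
                if cur.start <= prev.end:
                    raise ValueError(
                        f"{self.kit_name}: targets on {chrom} not merged/disjoint"
                    )
            merged[chrom] = ivs
        object.__setattr__(self, "targets", merged)

    @classmethod
    def from_intervals(
        cls, kit_name: str, intervals: Iterable[GenomeInterval]
    ) -> "CaptureDesign":
        grouped = _group_by_chrom(intervals)
        return cls(
            kit_name,
            {c: tuple(merge_intervals(ivs)) for c, ivs in sorted(grouped.items())},
        )

    def on_chrom(self, chrom: str) -> tuple[GenomeInterval, ...]:
        return self.targets.get(chrom, ())

    @property
    def total_target_bases(self) -> int:
        return sum(total_length(ivs) for ivs in self.targets.values())


_BED_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(path: str | Path, kit_name: str | None = None) -> CaptureDesign:
    """Read a BED3+ file into a merged :class:`CaptureDesign`.

    Track/browser/comment lines are skipped. A record with start >= end raises
    ``ValueError`` naming the offending line.
    """
    path = Path(path)
    intervals: list[GenomeInterval] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED record has fewer than 3 fields")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            intervals.append(GenomeInterval(chrom, start, end))
    if not intervals:
        logger.warning("BED file %s contains no records; empty design", path)
    return CaptureDesign.from_intervals(kit_name or path.stem, intervals)


def write_bed(design: CaptureDesign, path: str | Path) -> None:
    """Write a design's merged targets as BED3, chromosomes in sorted order."""
    path = Path(path)
    with path.open("w") as fh:
        for chrom in sorted(design.targets):
            for iv in design.targets[chrom]:
                fh.write(f"{chrom}\t{iv.start}\t{iv.end}\n")


def _parse_comma_list(text: str) -> list[int]:
    return [int(tok) for tok in text.strip().rstrip(",").split(",") if tok]


_GENEPRED_COLUMNS = (
    "gene_symbol",
    "chrom",
    "strand",
    "cdsStart",
    "cdsEnd",
    "exonStarts",
    "exonEnds",
)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a genePred-style tab-separated gene-model table.

    Expected columns (header optional; resolved by name when a header row is
    present): gene symbol, chrom, strand, cdsStart, cdsEnd, and comma-separated
    exonStarts/exonEnds. CDS intervals are derived as exon ∩ [cdsStart,
    cdsEnd); cdsStart == cdsEnd yields an empty CDS (non-coding gene).
    Duplicate gene symbols raise — callers must pre-deduplicate to one
    canonical transcript per gene.
    """
    path = Path(path)
    models: list[GeneModel] = []
    seen: set[str] = set()
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        return []
    header = lines[0].split("\t")
    if "exonStarts" in header:
        idx = {name: header.index(name) for name in _GENEPRED_COLUMNS}
        body = lines[1:]
    else:
        idx = {name: i for i, name in enumerate(_GENEPRED_COLUMNS)}
        body = lines
    for lineno, line in enumerate(body, start=1):
        fields = line.split("\t")
        symbol = fields[idx["gene_symbol"]]
        chrom = fields[idx["chrom"]]
        strand = fields[idx["strand"]]
        cds_start = int(fields[idx["cdsStart"]])
        cds_end = int(fields[idx["cdsEnd"]])
        starts = _parse_comma_list(fields[idx["exonStarts"]])
        ends = _parse_comma_list(fields[idx["exonEnds"]])
        if len(starts) != len(ends):
            raise ValueError(
                f"{path}: {symbol}: exonStarts/exonEnds length mismatch "
                f"({len(starts)} vs {len(ends)})"
            )
        if symbol in seen:
            raise ValueError(
                f"{path}: duplicate gene symbol {symbol!r}; "
                "pre-deduplicate to one canonical transcript per gene"
            )
        seen.add(symbol)
        exons = merge_intervals(
            [GenomeInterval(chrom, s, e) for s, e in zip(starts, ends)]
        )
        if cds_start < cds_end:
            cds = intersect_intervals(
                exons, [GenomeInterval(chrom, cds_start, cds_end)]
            )
        else:
            cds = []
        models.append(GeneModel(symbol, chrom, strand, tuple(exons), tuple(cds)))
    return models


def write_gene_models(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models in the genePred-style layout read_gene_models expects."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_GENEPRED_COLUMNS) + "\n")
        for m in models:
            if m.cds:
                cds_start, cds_end = m.cds[0].start, m.cds[-1].end
            else:
                cds_start = cds_end = m.exons[0].start
            starts = ",".join(str(iv.start) for iv in m.exons) + ","
            ends = ",".join(str(iv.end) for iv in m.exons) + ","
            fh.write(
                f"{m.gene_symbol}\t{m.chrom}\t{m.strand}\t{cds_start}\t{cds_end}"
                f"\t{starts}\t{ends}\n"
            )


def read_gene_models_bed(
    path: str | Path, cds_from_exons: bool = False
) -> list[GeneModel]:
    """Read per-gene canonical-exon BED records (name column = gene symbol).

    Each gene's exons are the merged intervals sharing its name. BED carries no
    CDS bounds: by default CDS is left empty; ``cds_from_exons=True`` treats
    the whole exon set as coding (appropriate for CDS-only BED bundles).
    """
    path = Path(path)
    per_gene: dict[str, list[GenomeInterval]] = {}
    chrom_strand: dict[str, tuple[str, str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: gene BED needs a name column")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
            if name in chrom_strand and chrom_strand[name][0] != chrom:
                raise ValueError(
                    f"{path}: gene {name!r} appears on multiple chromosomes"
                )
            chrom_strand.setdefault(name, (chrom, strand))
            per_gene.setdefault(name, []).append(GenomeInterval(chrom, start, end))
    models = []
    for name, ivs in per_gene.items():
        chrom, strand = chrom_strand[name]
        exons = tuple(merge_intervals(ivs))
        cds = exons if cds_from_exons else ()
        models.append(GeneModel(name, chrom, strand, exons, cds))
    return models
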