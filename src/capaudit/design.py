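"""Capture-design BED audit against gene annotations.

When a kit's probe target BED is available, undercoverage can be read off the
design itself: a gene (or exon) with less than 80% of its region bases inside
the merged targets is undercovered by design — absent if the overlap is
exactly zero, incomplete otherwise. The same status taxonomy is used by the
depth-based audit so kits with and without public BEDs are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from capaudit.coverage import AuditThresholds, DEFAULT_THRESHOLDS
from capaudit.intervals import CaptureDesign, GeneModel, GenomeInterval, total_length

STATUSES = ("covered", "undercovered_incomplete", "undercovered_absent")


@dataclass(frozen=True)
class DesignAuditRow:
    gene_symbol: str
    region_mode: str
    region_length: int
    overlap_bases: int
    covered_fraction: float
    status: str
    exon_index: int | None = None  # None for gene-level rows


def _pad_targets(
    targets: Sequence[GenomeInterval], pad: int
) -> list[GenomeInterval]:
    from capaudit.intervals import merge_intervals

    if pad == 0 or not targets:
        return list(targets)
    return merge_intervals(
        [GenomeInterval(iv.chrom, max(0, iv.start - pad), iv.end + pad) for iv in targets]
    )


def covered_fraction(
    gene: GeneModel,
    design: CaptureDesign,
    region_mode: str = "exon",
    pad: int = 0,
) -> float:
    """Fraction of the gene's region bases overlapped by the design targets.

    ``pad`` widens each target by that many bases on both sides before
    intersecting (real capture recovers some flanking sequence; default 0
    models the bare probe design).
    """
    region = gene.region(region_mode)
    length = total_length(region)
    if length == 0:
        raise ValueError(
            f"{gene.gene_symbol}: empty {region_mode} region (non-coding gene?)"
        )
    targets = _pad_targets(design.on_chrom(gene.chrom), pad)
    from capaudit.intervals import intersect_bases

    return intersect_bases(list(region), targets) / length


def _status(fraction: float, thresholds: AuditThresholds) -> str:
    if fraction >= thresholds.qualifying_frac:
        return "covered"
    return "undercovered_absent" if fraction == 0 else "undercovered_incomplete"


def audit_design(
    design: CaptureDesign,
    models: Sequence[GeneModel],
    region_mode: str = "exon",
    thresholds: AuditThresholds = DEFAULT_THRESHOLDS,
    pad: int = 0,
) -> tuple[list[DesignAuditRow], dict]:
    """Audit every gene model against a capture design.

    Returns one row per eligible gene plus a summary dict with counts per
    status. In CDS mode, genes with an empty CDS cannot be scored; they are
    excluded from the rows and listed in ``summary['skipped_no_cds']``.
    """
    if not models:
        raise ValueError("audit_design requires at least one gene model")
    rows: list[DesignAuditRow] = []
    skipped: list[str] = []
    for gene in sorted(models, key=lambda m: m.gene_symbol):
        region = gene.region(region_mode)
        if total_length(region) == 0:
            skipped.append(gene.gene_symbol)
            continue
        frac = covered_fraction(gene, design, region_mode, pad)
        length = gene.region_length(region_mode)
        rows.append(
            DesignAuditRow(
                gene.gene_symbol,
                region_mode,
                length,
                round(frac * length),
                frac,
                _status(frac, thresholds),
            )
        )
    counts = {s: sum(1 for r in rows if r.status == s) for s in STATUSES}
    summary = {
        "kit_name": design.kit_name,
        "region_mode": region_mode,
        "n_genes": len(rows),
        "n_undercovered": counts["undercovered_incomplete"]
        + counts["undercovered_absent"],
        "skipped_no_cds": skipped,
        **counts,
    }
    return rows, summary


def audit_exons(
    design: CaptureDesign,
    model: GeneModel,
    region_mode: str = "exon",
    thresholds: AuditThresholds = DEFAULT_THRESHOLDS,
    pad: int = 0,
) -> tuple[list[DesignAuditRow], bool]:
    """Per-exon covered fractions and statuses for one gene.

    Returns the per-exon rows (chromosomal order) and whether every exon in
    the chosen region mode is undercovered.
    """
    from capaudit.intervals import intersect_bases

    region = model.region(region_mode)
    if not region:
        raise ValueError(f"{model.gene_symbol}: no {region_mode} intervals")
    targets = _pad_targets(design.on_chrom(model.chrom), pad)
    rows = []
    for i, exon in enumerate(region):
        overlap = intersect_bases([exon], targets)
        frac = overlap / len(exon)
        rows.append(
            DesignAuditRow(
                model.gene_symbol,
                region_mode,
                len(exon),
                overlap,
                frac,
                _status(frac, thresholds),
                exon_index=i,
            )
        )
    all_under = all(r.status != "covered" for r in rows)
    return rows, all_under


def crossref_gene_list(
    rows: Sequence[DesignAuditRow],
    genes_of_interest: Sequence[str],
) -> tuple[list[DesignAuditRow], dict]:
    """Restrict an audit to a gene list (e.g. known cancer genes).

    Returns the matching rows and counts per status plus the list symbols not
    present in the audit (reported, not an error).
    """
    by_symbol = {r.gene_symbol: r for r in rows if r.exon_index is None}
    subset = [by_symbol[g] for g in genes_of_interest if g in by_symbol]
    not_found = sorted(set(genes_of_interest) - set(by_symbol))
    counts = {s: sum(1 for r in subset if r.status == s) for s in STATUSES}
    counts["not_found"] = not_found
    return subset, counts


def write_audit_tsv(
    rows: Sequence[DesignAuditRow],
    path: str | Path,
    thresholds: AuditThresholds = DEFAULT_THRESHOLDS,
    kit_name: str = "",
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# kit: {kit_name}; thresholds: {thresholds.describe()}\n")
        fh.write(
            "gene_symbol\tregion_mode\texon_index\tregion_length\t"
            "overlap_bases\tcovered_fraction\tstatus\n"
        )
        for r in rows:
            exon = "" if r.exon_index is None else str(r.exon_index)
            fh.write(
                f"{r.gene_symbol}\t{r.region_mode}\t{exon}\t{r.region_length}\t"
                f"{r.overlap_bases}\t{r.covered_fraction:.6g}\t{r.status}\n"
            )
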