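"""Kit attribution: join coverage sufficiency with sample→kit metadata.

The causal question is whether insufficiency segregates with the capture kit
a sample was sequenced with. ``kit_explains`` answers it with two set
equalities per cohort × gene × kit: do all insufficient samples use the kit,
and are all the kit's users insufficient? ``kit_association_test`` (an
optional extension, off by default in the pipeline) adds an exact 2×2 test
with Benjamini–Hochberg adjustment across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from capaudit.coverage import SampleCoverage
from capaudit.maf import CohortMutationTable

logger = logging.getLogger(__name__)

UNKNOWN_KIT = "Unknown"


@dataclass(frozen=True)
class KitAssignment:
    sample_id: str
    cohort_id: str
    kit_name: str
    center: str = ""


@dataclass(frozen=True)
class KitSummaryRow:
    cohort_id: str
    kit_name: str
    gene_symbol: str
    n_samples: int
    n_insufficient: int

    @property
    def insufficiency_fraction(self) -> float:
        return self.n_insufficient / self.n_samples


def read_kit_table(path: str | Path) -> list[KitAssignment]:
    """Read a kit-metadata TSV (sample_id, cohort, kit_name[, center])."""
    path = Path(path)
    rows: list[KitAssignment] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("sample_id"):
                continue
            fields = line.split("\t")
            center = fields[3] if len(fields) > 3 else ""
            rows.append(KitAssignment(fields[0], fields[1], fields[2], center))
    return rows


def write_kit_table(rows: Sequence[KitAssignment], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\tcohort\tkit_name\tcenter\n")
        for r in rows:
            fh.write(f"{r.sample_id}\t{r.cohort_id}\t{r.kit_name}\t{r.center}\n")


def join_kits(
    coverage: Sequence[SampleCoverage],
    kits: Sequence[KitAssignment],
) -> list[SampleCoverage]:
    """Annotate coverage rows with each sample's capture kit.

    Samples absent from the kit table are annotated ``Unknown`` (they form
    their own stratum downstream, so conservation over kits holds). A sample
    listed twice with conflicting kits raises.
    """
    kit_of: dict[str, str] = {}
    for k in kits:
        if k.sample_id in kit_of and kit_of[k.sample_id] != k.kit_name:
            raise ValueError(
                f"sample {k.sample_id} assigned to conflicting kits "
                f"{kit_of[k.sample_id]!r} and {k.kit_name!r}"
            )
        kit_of[k.sample_id] = k.kit_name
    out: list[SampleCoverage] = []
    n_unknown = 0
    for row in coverage:
        kit = kit_of.get(row.sample_id)
        if kit is None:
            kit = UNKNOWN_KIT
            n_unknown += 1
        out.append(
            SampleCoverage(
                row.sample_id,
                row.gene_symbol,
                row.read_count,
                row.avg_exon_coverage,
                row.sufficient,
                row.cohort_id,
                kit,
            )
        )
    if n_unknown:
        logger.warning("%d coverage rows had no kit metadata (kit=Unknown)", n_unknown)
    return out


def kit_summary(
    annotated: Sequence[SampleCoverage], gene: str
) -> list[KitSummaryRow]:
    """Per cohort × kit insufficiency counts for one gene, sorted (cohort, kit)."""
    rows = [r for r in annotated if r.gene_symbol == gene]
    if not rows:
        raise ValueError(f"no coverage rows for gene {gene!r}")
    groups: dict[tuple[str, str], list[SampleCoverage]] = {}
    for r in rows:
        groups.setdefault((r.cohort_id, r.kit_name), []).append(r)
    return [
        KitSummaryRow(
            cohort,
            kit,
            gene,
            len(grp),
            sum(1 for r in grp if not r.sufficient),
        )
        for (cohort, kit), grp in sorted(groups.items())
    ]


def kit_explains(
    annotated: Sequence[SampleCoverage],
    gene: str,
    cohort: str,
    kit: str,
) -> tuple[bool, bool]:
    """Does kit usage exactly delineate insufficiency in a cohort?

    Returns ``(all_insufficient_use_kit, all_kit_users_insufficient)``. The
    kit must be present in the cohort's rows for the gene.
    """
    rows = [r for r in annotated if r.gene_symbol == gene and r.cohort_id == cohort]
    kit_rows = [r for r in rows if r.kit_name == kit]
    if not kit_rows:
        raise ValueError(f"kit {kit!r} has no samples in cohort {cohort!r} for {gene!r}")
    insufficient = {r.sample_id for r in rows if not r.sufficient}
    kit_users = {r.sample_id for r in kit_rows}
    all_insufficient_use_kit = insufficient <= kit_users
    all_kit_users_insufficient = all(not r.sufficient for r in kit_rows)
    return all_insufficient_use_kit, all_kit_users_insufficient


def kit_association_test(
    annotated: Sequence[SampleCoverage],
    genes: Sequence[str],
    cohort: str,
    kit: str,
    alpha: float = 0.05,
) -> list[dict]:
    """Exact 2×2 test of kit vs insufficiency per gene, BH-adjusted.

    For each gene, the cohort's samples form a (kit vs other) × (insufficient
    vs sufficient) table tested with Fisher's exact conditional test. Genes
    with a degenerate margin (all samples in one row/column) are flagged with
    no p-value and excluded from adjustment. This is an extension beyond the
    tabulations the audit itself relies on.
    """
    results: list[dict] = []
    for gene in genes:
        rows = [r for r in annotated if r.gene_symbol == gene and r.cohort_id == cohort]
        if not rows:
            results.append({"gene": gene, "degenerate": True, "note": "no rows"})
            continue
        a = sum(1 for r in rows if r.kit_name == kit and not r.sufficient)
        b = sum(1 for r in rows if r.kit_name == kit and r.sufficient)
        c = sum(1 for r in rows if r.kit_name != kit and not r.sufficient)
        d = sum(1 for r in rows if r.kit_name != kit and r.sufficient)
        table = np.array([[a, b], [c, d]])
        if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
            results.append(
                {"gene": gene, "table": table.tolist(), "degenerate": True}
            )
            continue
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        results.append(
            {
                "gene": gene,
                "table": table.tolist(),
                "odds_ratio": float(odds) if np.isfinite(odds) else float("inf"),
                "p_value": float(p),
                "degenerate": False,
            }
        )
    tested = [r for r in results if not r.get("degenerate")]
    if tested:
        pvals = np.array([r["p_value"] for r in tested])
        order = np.argsort(pvals)
        m = len(pvals)
        q = np.empty(m)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            running = min(running, pvals[i] * m / (rank_pos + 1))
            q[i] = running
        for r, qv in zip(tested, q):
            r["q_value"] = float(qv)
            r["significant"] = bool(qv <= alpha)
    return results


def status_matrix(
    annotated: Sequence[SampleCoverage],
    tables: Mapping[str, CohortMutationTable],
    genes: Sequence[str],
) -> dict[str, dict[str, object]]:
    """Per gene × cohort: fraction of samples with sufficient coverage.

    Cohorts with at least one non-silent call for the gene are marked
    ``"not_considered"`` — observed mutations mean absence is not the
    question there. Cohorts with no coverage rows are omitted.
    """
    matrix: dict[str, dict[str, object]] = {}
    cohorts = sorted({r.cohort_id for r in annotated})
    for gene in genes:
        row: dict[str, object] = {}
        for cohort in cohorts:
            rows = [
                r
                for r in annotated
                if r.gene_symbol == gene and r.cohort_id == cohort
            ]
            if not rows:
                continue
            table = tables.get(cohort)
            if table is not None and table.n_mutated(gene) >= 1:
                row[cohort] = "not_considered"
            else:
                row[cohort] = sum(1 for r in rows if r.sufficient) / len(rows)
        matrix[gene] = row
    return matrix


def write_status_matrix(
    matrix: Mapping[str, Mapping[str, object]], path: str | Path
) -> None:
    path = Path(path)
    cohorts = sorted({c for row in matrix.values() for c in row})
    with path.open("w") as fh:
        fh.write("gene_symbol\t" + "\t".join(cohorts) + "\n")
        for gene in sorted(matrix):
            cells = []
            for c in cohorts:
                v = matrix[gene].get(c, "")
                cells.append(v if isinstance(v, str) else f"{v:.6g}")
            fh.write(gene + "\t" + "\t".join(cells) + "\n")


def write_kit_summary(
    rows: Sequence[KitSummaryRow], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            "cohort\tkit_name\tgene_symbol\tn_samples\tn_insufficient\t"
            "insufficiency_fraction\n"
        )
        for r in rows:
            fh.write(
                f"{r.cohort_id}\t{r.kit_name}\t{r.gene_symbol}\t{r.n_samples}\t"
                f"{r.n_insufficient}\t{r.insufficiency_fraction:.6g}\n"
            )
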