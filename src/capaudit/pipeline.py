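"""In-memory end-to-end study: simulate, screen, audit, attribute, compare.

This is the library counterpart of the CLI `all` subcommand: it runs every
stage over one simulated world and scores the results against the planted
ground truth, returning plain dicts that drivers can tabulate or serialise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from capaudit.coverage import (
    AuditThresholds,
    DEFAULT_THRESHOLDS,
    call_undercovered_gene,
    undercovered_cohort,
)
from capaudit.design import audit_design
from capaudit.kits import kit_explains
from capaudit.maf import CohortMutationTable, build_cohort_table, screen_candidates
from capaudit.simulate import SimulationConfig, SyntheticBundle, simulate_bundle


@dataclass
class StudyResult:
    """Per-stage outputs of one simulated study plus truth comparisons."""

    seed: int
    candidates: set[str]
    expected_candidates: set[str]
    undercovered_pairs: set[tuple[str, str]]
    design_status_matches: bool
    kit_explains_ok: bool
    summary: dict = field(default_factory=dict)

    @property
    def screen_exact(self) -> bool:
        return self.candidates == self.expected_candidates

    @property
    def coverage_calls_absent_cohorts(self) -> bool:
        return self.summary["missing_undercovered_pairs"] == 0

    @property
    def all_ok(self) -> bool:
        return (
            self.screen_exact
            and self.coverage_calls_absent_cohorts
            and self.design_status_matches
            and self.kit_explains_ok
        )


def cohort_tables(bundle: SyntheticBundle) -> dict[str, CohortMutationTable]:
    return {
        cohort: build_cohort_table(records, bundle.rosters[cohort], cohort)
        for cohort, records in bundle.maf_records.items()
    }


def run_study(
    config: SimulationConfig,
    thresholds: AuditThresholds = DEFAULT_THRESHOLDS,
    min_rate: float = 0.05,
    min_zero_cohorts: int = 3,
) -> StudyResult:
    """Simulate one world and run every audit stage against its ground truth.

    Scores:

    * **screen** — candidate genes from the coverage-censored MAFs must equal
      the genes whose censoring ground truth has >= ``min_zero_cohorts``
      censored cohorts (and in particular contain no fully covered gene);
    * **coverage** — each (absent gene, cohort on the defective kit) pair
      must be called an undercovered cohort from per-sample sufficiency;
    * **design** — BED-audit statuses must equal the planted design statuses;
    * **kits** — for absent genes, the defective kit must explain
      insufficiency in mixed analyses (every kit user insufficient).
    """
    bundle = simulate_bundle(config)
    truth = bundle.truth
    tables = cohort_tables(bundle)
    candidates = {
        c.gene_symbol
        for c in screen_candidates(
            list(tables.values()), min_rate=min_rate, min_zero_cohorts=min_zero_cohorts
        )
    }
    expected = truth.censored_genes(min_zero_cohorts)

    # undercovered cohorts from per-sample sufficiency flags
    undercovered_pairs: set[tuple[str, str]] = set()
    flags: dict[tuple[str, str], list[bool]] = {}
    for row in bundle.coverage:
        flags.setdefault((row.gene_symbol, row.cohort_id), []).append(row.sufficient)
    for (gene, cohort), fl in flags.items():
        if undercovered_cohort(fl, thresholds):
            undercovered_pairs.add((gene, cohort))
    kit_of_cohort = {c.name: c.kit_name for c in config.cohorts}
    missing = 0
    for kit, absent_genes in truth.absent.items():
        cohorts = [c for c, k in kit_of_cohort.items() if k == kit]
        for g in absent_genes:
            for cohort in cohorts:
                if (g, cohort) not in undercovered_pairs:
                    missing += 1

    # depth-based gene statuses agree with planted design statuses per cohort
    design_ok = True
    for kit, design in bundle.designs.items():
        rows, _ = audit_design(design, bundle.models, config.region_mode, thresholds)
        for r in rows:
            if r.status != truth.design_status(kit, r.gene_symbol, thresholds.qualifying_frac):
                design_ok = False

    # cross-check: depth audit of the mean profiles agrees with design audit
    depth_matches = 0
    depth_total = 0
    for (cohort, gene), profile in bundle.mean_profiles.items():
        kit = kit_of_cohort[cohort]
        call = call_undercovered_gene(np.asarray(profile), gene, thresholds)
        depth_total += 1
        if call.status == truth.design_status(kit, gene, thresholds.qualifying_frac):
            depth_matches += 1

    # kit attribution on absent genes in any cohort mix
    kits_ok = True
    for kit, absent_genes in truth.absent.items():
        cohorts = [c for c, k in kit_of_cohort.items() if k == kit]
        for g in absent_genes:
            for cohort in cohorts:
                _, all_users_insufficient = kit_explains(bundle.coverage, g, cohort, kit)
                if not all_users_insufficient:
                    kits_ok = False

    n_false_pos = len(candidates - expected)
    return StudyResult(
        seed=config.seed,
        candidates=candidates,
        expected_candidates=expected,
        undercovered_pairs=undercovered_pairs,
        design_status_matches=design_ok,
        kit_explains_ok=kits_ok,
        summary={
            "n_candidates": len(candidates),
            "n_expected": len(expected),
            "n_false_positive_candidates": n_false_pos,
            "missing_undercovered_pairs": missing,
            "depth_vs_design_agreement": depth_matches / max(depth_total, 1),
            "n_maf_rows": sum(len(v) for v in bundle.maf_records.values()),
        },
    )
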