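"""Cohort mutation tables and the suspicious-absence screen.

A gene that is commonly mutated across tumor types but has *zero* called
mutations in several cohorts is a candidate for a measurement artifact rather
than real biology. The screen keeps genes whose pooled non-silent mutation
rate over cohorts with at least one call is at least ``min_rate`` (default
5%) and that have at least ``min_zero_cohorts`` (default 3) cohorts with no
calls at all — the cohort-count floor discards absences that small cohorts
would produce by chance even at a 5% true rate.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Variant_Classification terms counted as non-silent. The complement
#: (Silent, Intron, UTRs, Flank, IGR, RNA, ...) never contributes a call.
NONSILENT_CLASSIFICATIONS = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "In_Frame_Ins",
        "In_Frame_Del",
        "Splice_Site",
        "Translation_Start_Site",
    }
)

_SILENT_CLASSIFICATIONS = frozenset(
    {
        "Silent",
        "Intron",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "IGR",
        "RNA",
        "Targeted_Region",
        "De_novo_Start_InFrame",
        "De_novo_Start_OutOfFrame",
    }
)


def is_nonsilent(
    variant_classification: str,
    nonsilent_terms: frozenset[str] = NONSILENT_CLASSIFICATIONS,
) -> bool:
    """True iff the MAF classification term is in the non-silent set.

    Unrecognized terms are treated as silent with a warning, so malformed
    rows can never create a spurious mutation call.
    """
    if variant_classification in nonsilent_terms:
        return True
    if variant_classification not in _SILENT_CLASSIFICATIONS:
        logger.warning(
            "unrecognized Variant_Classification %r treated as silent",
            variant_classification,
        )
    return False


@dataclass(frozen=True)
class MafRecord:
    gene_symbol: str
    variant_classification: str
    sample_id: str
    cohort_id: str

    def __post_init__(self) -> None:
        for name in ("gene_symbol", "variant_classification", "sample_id", "cohort_id"):
            if not getattr(self, name):
                raise ValueError(f"MafRecord.{name} must be non-empty")


@dataclass
class CohortMutationTable:
    """Per cohort: the sample roster and, per gene, samples with >=1 non-silent call."""

    cohort_id: str
    roster: frozenset[str]
    mutated: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.roster:
            raise ValueError(f"cohort {self.cohort_id}: roster must be non-empty")
        for gene, samples in self.mutated.items():
            if not samples <= self.roster:
                raise ValueError(
                    f"cohort {self.cohort_id}: mutated samples for {gene} "
                    "not all in roster"
                )

    @property
    def n_samples(self) -> int:
        return len(self.roster)

    def n_mutated(self, gene: str) -> int:
        return len(self.mutated.get(gene, frozenset()))


@dataclass(frozen=True)
class CandidateGene:
    gene_symbol: str
    zero_cohorts: tuple[str, ...]
    pooled_rate: float
    all_zero: bool = False


def build_cohort_table(
    records: Iterable[MafRecord], roster: Iterable[str], cohort_id: str
) -> CohortMutationTable:
    """Aggregate MAF records into a cohort table with set semantics.

    Each sample counts at most once per gene regardless of row multiplicity;
    samples whose rows are all silent do not enter any mutated set. Records
    for samples missing from the roster are added to it with a warning so
    denominators stay conservative rather than silently dropping calls.
    """
    roster_set = set(roster)
    if not roster_set:
        raise ValueError(f"cohort {cohort_id}: empty roster")
    mutated: dict[str, set[str]] = {}
    extra: set[str] = set()
    for rec in records:
        if rec.cohort_id != cohort_id:
            continue
        if rec.sample_id not in roster_set:
            extra.add(rec.sample_id)
            roster_set.add(rec.sample_id)
        if is_nonsilent(rec.variant_classification):
            mutated.setdefault(rec.gene_symbol, set()).add(rec.sample_id)
    if extra:
        logger.warning(
            "cohort %s: %d MAF samples absent from roster, added: %s",
            cohort_id,
            len(extra),
            sorted(extra)[:5],
        )
    return CohortMutationTable(
        cohort_id,
        frozenset(roster_set),
        {g: frozenset(s) for g, s in mutated.items()},
    )


def pooled_mutation_rate(
    gene: str,
    tables: Sequence[CohortMutationTable],
    method: str = "pooled",
) -> tuple[float, bool]:
    """Mutation rate over cohorts that have at least one call for the gene.

    ``method='pooled'`` (default): total mutated samples / total roster size
    over the non-zero cohorts. ``method='mean'``: unweighted mean of per-cohort
    rates over the same cohorts. Returns ``(rate, all_zero)`` where
    ``all_zero`` flags a gene with no call in any supplied cohort (rate 0).
    """
    if not tables:
        raise ValueError("pooled_mutation_rate requires at least one cohort table")
    if method not in ("pooled", "mean"):
        raise ValueError(f"unknown rate method {method!r}")
    nonzero = [t for t in tables if t.n_mutated(gene) >= 1]
    if not nonzero:
        return 0.0, True
    if method == "pooled":
        num = sum(t.n_mutated(gene) for t in nonzero)
        den = sum(t.n_samples for t in nonzero)
        return num / den, False
    rates = [t.n_mutated(gene) / t.n_samples for t in nonzero]
    return sum(rates) / len(rates), False


def screen_candidates(
    tables: Sequence[CohortMutationTable],
    min_rate: float = 0.05,
    min_zero_cohorts: int = 3,
    rate_method: str = "pooled",
) -> list[CandidateGene]:
    """Genes with suspicious cohort-specific mutational absence.

    A gene is retained iff its mutation rate over non-zero cohorts is at least
    ``min_rate`` and at least ``min_zero_cohorts`` cohorts have zero non-silent
    calls for it. Output is sorted by gene symbol and carries each gene's
    zero-call cohort list.
    """
    if not 0 < min_rate <= 1:
        raise ValueError(f"min_rate must be in (0, 1], got {min_rate}")
    if len(tables) < min_zero_cohorts:
        raise ValueError(
            f"need at least min_zero_cohorts={min_zero_cohorts} cohorts, "
            f"got {len(tables)}"
        )
    genes = sorted({g for t in tables for g in t.mutated})
    out: list[CandidateGene] = []
    for gene in genes:
        zero = tuple(
            sorted(t.cohort_id for t in tables if t.n_mutated(gene) == 0)
        )
        if len(zero) < min_zero_cohorts:
            continue
        rate, all_zero = pooled_mutation_rate(gene, tables, method=rate_method)
        if rate >= min_rate:
            out.append(CandidateGene(gene, zero, rate, all_zero))
    return out


# ---------------------------------------------------------------------------
# I/O: MAF, roster, candidate tables

_MAF_REQUIRED = ("Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode")


def read_maf(path: str | Path, cohort_id: str) -> list[MafRecord]:
    """Read a tab-separated MAF file ('#' comment lines skipped).

    Only Hugo_Symbol, Variant_Classification and Tumor_Sample_Barcode are
    required; all other columns are ignored.
    """
    path = Path(path)
    records: list[MafRecord] = []
    with path.open() as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in _MAF_REQUIRED if c not in header]
                if missing:
                    raise ValueError(f"{path}: missing MAF columns {missing}")
                idx = tuple(header.index(c) for c in _MAF_REQUIRED)
                continue
            records.append(
                MafRecord(fields[idx[0]], fields[idx[1]], fields[idx[2]], cohort_id)
            )
    return records


def read_roster(path: str | Path) -> dict[str, set[str]]:
    """Read a roster TSV (sample_id, cohort_id) into cohort -> sample set."""
    path = Path(path)
    rosters: dict[str, set[str]] = {}
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("sample_id"):
                continue
            sample_id, cohort_id = line.split("\t")[:2]
            rosters.setdefault(cohort_id, set()).add(sample_id)
    return rosters


def write_candidates(
    candidates: Sequence[CandidateGene], path: str | Path
) -> None:
    """Write the candidate-gene table (gene, zero cohorts, pooled rate)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_symbol\tn_zero_cohorts\tzero_cohorts\tpooled_rate\n")
        for c in candidates:
            fh.write(
                f"{c.gene_symbol}\t{len(c.zero_cohorts)}\t"
                f"{','.join(c.zero_cohorts)}\t{c.pooled_rate:.6g}\n"
            )


def classification_log_summary(records: Iterable[MafRecord]) -> Counter:
    """Counts per Variant_Classification term, for attrition logging."""
    return Counter(r.variant_classification for r in records)
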