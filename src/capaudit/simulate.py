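"""Seeded generator of kit designs, depth tracks and coverage-censored MAFs.

The generator emulates the causal structure under audit: cohorts of tumor
samples are each sequenced with one capture kit; a kit's probe design misses
some genes entirely and tiles others only partially; read depth is high
(~100x, the typical whole-exome average) on probe-covered bases and near zero
off probe; every gene mutates at its true per-sample rate, but a mutation
only reaches the cohort's mutation table if the sample's average depth over
the gene clears the caller-sensitivity threshold (25x step rule). Ground
truth — which genes each kit misses, each planted design fraction, and which
cohort × gene cells are depth-censored — is recorded alongside the emitted
files so every pipeline stage can be checked against what was planted.

Depth is simulated per base directly (independent Poisson or negative
binomial counts) rather than via synthetic reads, for speed; a small SAM
emitter is provided separately to exercise the alignment-filtering and
depth-piling code paths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from capaudit.coverage import DepthTrack, RegionIndex, SampleCoverage
from capaudit.intervals import (
    CaptureDesign,
    GeneModel,
    GenomeInterval,
    merge_intervals,
    total_length,
    write_bed,
    write_gene_models,
)
from capaudit.kits import KitAssignment, write_kit_table
from capaudit.maf import NONSILENT_CLASSIFICATIONS, MafRecord

_NONSILENT = tuple(sorted(NONSILENT_CLASSIFICATIONS))


@dataclass(frozen=True)
class KitSpec:
    """Planted probe design for one kit: which genes it misses or half-covers."""

    kit_name: str
    absent_frac: float = 0.0
    partial_frac: float = 0.0
    partial_range: tuple[float, float] = (0.3, 0.7)

    def __post_init__(self) -> None:
        if not 0 <= self.absent_frac <= 1 or not 0 <= self.partial_frac <= 1:
            raise ValueError("design fractions must lie in [0, 1]")
        if self.absent_frac + self.partial_frac > 1:
            raise ValueError("absent_frac + partial_frac must be <= 1")
        lo, hi = self.partial_range
        if not 0 < lo <= hi < 1:
            raise ValueError("partial_range must satisfy 0 < lo <= hi < 1")


@dataclass(frozen=True)
class CohortSpec:
    name: str
    n_samples: int
    kit_name: str

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"cohort {self.name}: n_samples must be >= 1")


def _default_kits() -> list[KitSpec]:
    return [
        KitSpec("kit_biased", absent_frac=0.05, partial_frac=0.05),
        KitSpec("kit_complete"),
    ]


def _default_cohorts() -> list[CohortSpec]:
    return [
        CohortSpec(f"C{i + 1}", 200, "kit_biased" if i < 3 else "kit_complete")
        for i in range(6)
    ]


@dataclass
class SimulationConfig:
    """The stated world: cohort sizes, kit defects, depth model, censoring.

    Defaults plant the reference scenario: 100 genes, six cohorts of 200
    samples, three on a kit missing 5 genes outright and half-covering 5
    more; 100x mean on-probe depth against 0.5x off-probe; 10% true per-gene
    mutation rate; calls censored when a sample's average gene depth falls
    below 25x. Gene exon content is drawn from 500–3000 bp (the scale of
    typical canonical coding genes).
    """

    n_genes: int = 100
    gene_length_range: tuple[int, int] = (500, 3000)
    exons_per_gene_range: tuple[int, int] = (1, 6)
    noncoding_frac: float = 0.0
    utr_frac: float = 0.1
    cohorts: list[CohortSpec] = field(default_factory=_default_cohorts)
    kits: list[KitSpec] = field(default_factory=_default_kits)
    depth_model: str = "poisson"
    mean_on: float = 100.0
    mean_off: float = 0.5
    dispersion: float = 0.1
    mutation_rate: float | Mapping[str, float] = 0.10
    censor_rule: str = "step_at_min_avg_depth"
    min_avg_depth: float = 25.0
    read_length: int = 100
    region_mode: str = "exon"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.gene_length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid gene_length_range")
        elo, ehi = self.exons_per_gene_range
        if not 1 <= elo <= ehi:
            raise ValueError("invalid exons_per_gene_range")
        if self.depth_model not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown depth_model {self.depth_model!r}")
        if self.depth_model == "negative_binomial" and self.dispersion <= 0:
            raise ValueError("negative_binomial requires dispersion > 0")
        if not self.mean_on > self.mean_off >= 0:
            raise ValueError("require mean_on > mean_off >= 0")
        if self.censor_rule not in ("step_at_min_avg_depth", "none"):
            raise ValueError(f"unknown censor_rule {self.censor_rule!r}")
        kit_names = {k.kit_name for k in self.kits}
        for c in self.cohorts:
            if c.kit_name not in kit_names:
                raise ValueError(f"cohort {c.name} uses unknown kit {c.kit_name!r}")

    def rate_of(self, gene_symbol: str) -> float:
        if isinstance(self.mutation_rate, Mapping):
            return float(self.mutation_rate.get(gene_symbol, 0.0))
        return float(self.mutation_rate)


@dataclass
class GroundTruth:
    """What was planted: per-kit design defects and per-cell censoring."""

    absent: dict[str, list[str]] = field(default_factory=dict)
    partial: dict[str, dict[str, float]] = field(default_factory=dict)
    design_fraction: dict[str, dict[str, float]] = field(default_factory=dict)
    true_rate: dict[str, float] = field(default_factory=dict)
    censored: dict[str, dict[str, bool]] = field(default_factory=dict)

    def design_status(
        self, kit: str, gene: str, qualifying_frac: float = 0.80
    ) -> str:
        frac = self.design_fraction[kit][gene]
        if frac >= qualifying_frac:
            return "covered"
        return "undercovered_absent" if frac == 0 else "undercovered_incomplete"

    def censored_genes(self, min_cohorts: int = 1) -> set[str]:
        counts: dict[str, int] = {}
        for per_gene in self.censored.values():
            for gene, flag in per_gene.items():
                if flag:
                    counts[gene] = counts.get(gene, 0) + 1
        return {g for g, n in counts.items() if n >= min_cohorts}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Genome and design generation


def make_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[GeneModel]:
    """Non-overlapping synthetic gene models on synthetic chromosomes.

    Each gene's total exon content is uniform in ``gene_length_range`` and
    split across a uniform number of exons; a ``utr_frac`` share of exon bases
    at each end is excluded from the CDS, and a ``noncoding_frac`` share of
    genes carries no CDS at all. Deterministic under the config seed.
    """
    rng = rng or np.random.default_rng(config.seed)
    models: list[GeneModel] = []
    genes_per_chrom = 25
    pos = 0
    for i in range(config.n_genes):
        chrom = f"chrS{i // genes_per_chrom + 1}"
        if i % genes_per_chrom == 0:
            pos = 1000
        total = int(rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1))
        n_exons = int(
            rng.integers(config.exons_per_gene_range[0], config.exons_per_gene_range[1] + 1)
        )
        n_exons = min(n_exons, total)  # every exon needs >= 1 base
        # split total exon bases into n_exons positive parts
        cuts = np.sort(rng.choice(np.arange(1, total), size=n_exons - 1, replace=False)) if n_exons > 1 else np.array([], dtype=int)
        lengths = np.diff(np.concatenate([[0], cuts, [total]])).astype(int)
        exons = []
        p = pos
        for L in lengths:
            exons.append(GenomeInterval(chrom, p, p + int(L)))
            p += int(L) + int(rng.integers(100, 1001))  # intron
        gene_end = exons[-1].end
        symbol = f"G{i + 1:04d}"
        noncoding = rng.random() < config.noncoding_frac
        if noncoding:
            cds: tuple[GenomeInterval, ...] = ()
        else:
            trim = int(round(config.utr_frac * total))
            cds_span_start = _offset_to_coord(exons, trim)
            cds_span_end = _offset_to_coord(exons, total - trim)
            if cds_span_start >= cds_span_end:
                cds_span_start, cds_span_end = exons[0].start, exons[-1].end
            from capaudit.intervals import intersect_intervals

            cds = tuple(
                intersect_intervals(exons, [GenomeInterval(chrom, cds_span_start, cds_span_end)])
            )
        models.append(GeneModel(symbol, chrom, "+" if rng.random() < 0.5 else "-", tuple(exons), cds))
        pos = gene_end + int(rng.integers(1000, 5001))  # intergenic gap
    return models


def _offset_to_coord(exons: Sequence[GenomeInterval], offset: int) -> int:
    """Genomic coordinate of the given concatenated-exon base offset."""
    for iv in exons:
        if offset < len(iv):
            return iv.start + offset
        offset -= len(iv)
    return exons[-1].end


def make_design(
    models: Sequence[GeneModel],
    kit_spec: KitSpec,
    rng: np.random.Generator | int | None = None,
    region_mode: str = "exon",
) -> tuple[CaptureDesign, GroundTruth]:
    """A capture design with planted absent / partial / fully tiled genes.

    Absent genes get zero targets; each partial gene is tiled from its
    region's 5'-most base until a uniform-random fraction of its bases is
    covered; all other genes are tiled exactly. The returned ground truth
    records the gene assignment and the realized per-gene design fraction.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = len(models)
    n_absent = int(round(kit_spec.absent_frac * n))
    n_partial = int(round(kit_spec.partial_frac * n))
    order = rng.permutation(n)
    absent_idx = set(order[:n_absent].tolist())
    partial_idx = set(order[n_absent : n_absent + n_partial].tolist())
    targets: list[GenomeInterval] = []
    truth = GroundTruth(
        absent={kit_spec.kit_name: []},
        partial={kit_spec.kit_name: {}},
        design_fraction={kit_spec.kit_name: {}},
    )
    for i, gene in enumerate(sorted(models, key=lambda m: m.gene_symbol)):
        region = list(gene.region(region_mode)) or list(gene.exons)
        length = total_length(region)
        if i in absent_idx:
            truth.absent[kit_spec.kit_name].append(gene.gene_symbol)
            truth.design_fraction[kit_spec.kit_name][gene.gene_symbol] = 0.0
            continue
        if i in partial_idx:
            f = float(rng.uniform(*kit_spec.partial_range))
            budget = int(round(f * length))
            covered = _tile_prefix(region, budget)
            truth.partial[kit_spec.kit_name][gene.gene_symbol] = f
            truth.design_fraction[kit_spec.kit_name][gene.gene_symbol] = (
                total_length(covered) / length
            )
            targets.extend(covered)
        else:
            truth.design_fraction[kit_spec.kit_name][gene.gene_symbol] = 1.0
            targets.extend(region)
    truth.absent[kit_spec.kit_name].sort()
    return CaptureDesign.from_intervals(kit_spec.kit_name, targets), truth


def _tile_prefix(region: Sequence[GenomeInterval], budget: int) -> list[GenomeInterval]:
    out: list[GenomeInterval] = []
    for iv in region:
        if budget <= 0:
            break
        take = min(budget, len(iv))
        out.append(GenomeInterval(iv.chrom, iv.start, iv.start + take))
        budget -= take
    return out


# ---------------------------------------------------------------------------
# Depth simulation


def _coverage_mask(gene: GeneModel, design: CaptureDesign, region_mode: str) -> np.ndarray:
    index = RegionIndex(gene, region_mode)
    mask = np.zeros(index.length, dtype=bool)
    for t in design.on_chrom(gene.chrom):
        for lo, hi in index.project(t.start, t.end):
            mask[lo:hi] = True
    return mask


def _draw_depth(
    mean_vec: np.ndarray,
    size: tuple[int, ...],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    if config.depth_model == "poisson":
        return rng.poisson(lam=mean_vec, size=size)
    # NB parameterised by mean m and dispersion a: var = m + a m^2
    r = 1.0 / config.dispersion
    mean = np.broadcast_to(mean_vec, size)
    p = r / (r + np.maximum(mean, 1e-12))
    out = np.zeros(size, dtype=np.int64)
    nz = mean > 0
    out[nz] = rng.negative_binomial(r, p[nz])
    return out


def simulate_depth(
    models: Sequence[GeneModel],
    design: CaptureDesign,
    n_samples: int,
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    sample_ids: Sequence[str] | None = None,
    region_mode: str | None = None,
) -> dict[str, dict[str, DepthTrack]]:
    """Per-sample, per-gene depth tracks under a kit design.

    Each base draws independently from the configured count distribution with
    mean ``mean_on`` if the base lies inside a design target and ``mean_off``
    otherwise. Deterministic under a fixed generator state.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    region_mode = region_mode or config.region_mode
    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    out: dict[str, dict[str, DepthTrack]] = {sid: {} for sid in sample_ids}
    for gene in models:
        mask = _coverage_mask(gene, design, region_mode)
        mean_vec = np.where(mask, config.mean_on, config.mean_off)
        mat = _draw_depth(mean_vec, (n_samples, mask.size), config, rng)
        for sid, row in zip(sample_ids, mat):
            out[sid][gene.gene_symbol] = DepthTrack(gene.gene_symbol, region_mode, row)
    return out


# ---------------------------------------------------------------------------
# Cohort simulation (memory-bounded end-to-end bundle)


@dataclass
class SyntheticBundle:
    """Everything one simulated study produces, plus its ground truth."""

    config: SimulationConfig
    models: list[GeneModel]
    designs: dict[str, CaptureDesign]
    rosters: dict[str, list[str]]
    kit_assignments: list[KitAssignment]
    maf_records: dict[str, list[MafRecord]]
    coverage: list[SampleCoverage]
    mean_profiles: dict[tuple[str, str], np.ndarray]
    truth: GroundTruth

    def write(self, outdir: str | Path, include_depth: bool = False) -> None:
        """Emit the bundle as plain-text files (MAF, TSVs, BEDs, JSON)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gene_models(self.models, outdir / "gene_models.tsv")
        for kit, design in self.designs.items():
            write_bed(design, outdir / f"design_{kit}.bed")
        with (outdir / "roster.tsv").open("w") as fh:
            fh.write("sample_id\tcohort_id\n")
            for cohort, samples in sorted(self.rosters.items()):
                for sid in samples:
                    fh.write(f"{sid}\t{cohort}\n")
        write_kit_table(self.kit_assignments, outdir / "kits.tsv")
        for cohort, records in sorted(self.maf_records.items()):
            with (outdir / f"{cohort}.maf").open("w") as fh:
                fh.write("#version synthetic\n")
                fh.write("Hugo_Symbol\tVariant_Classification\tTumor_Sample_Barcode\n")
                for r in records:
                    fh.write(
                        f"{r.gene_symbol}\t{r.variant_classification}\t{r.sample_id}\n"
                    )
        from capaudit.coverage import write_coverage_tsv

        write_coverage_tsv(self.coverage, outdir / "coverage.tsv")
        self.truth.to_json(outdir / "ground_truth.json")
        if include_depth:
            from capaudit.coverage import write_depth_tsv

            for cohort in sorted(self.rosters):
                tracks = {
                    g: DepthTrack(g, self.config.region_mode, prof)
                    for (c, g), prof in self.mean_profiles.items()
                    if c == cohort
                }
                write_depth_tsv(
                    outdir / f"mean_depth_{cohort}.tsv",
                    self.models,
                    {f"{cohort}_mean": tracks},
                    self.config.region_mode,
                )


def simulate_maf(
    models: Sequence[GeneModel],
    cohorts: Sequence[CohortSpec],
    config: SimulationConfig,
    avg_depths: Mapping[str, Mapping[str, np.ndarray]] | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[dict[str, list[MafRecord]], dict[str, list[str]], GroundTruth]:
    """Coverage-censored MAF records, rosters and censoring ground truth.

    Each sample × gene mutates with the gene's true rate; under the step rule
    a mutation reaches the MAF only when that sample's average region depth is
    at least ``min_avg_depth``. ``avg_depths[cohort][gene]`` supplies the
    per-sample averages (as produced by the depth simulation); when absent,
    averages are drawn from the same count model analytically aggregated over
    the gene's bases. The censoring ground truth is deterministic: a cohort ×
    gene cell is censored when the kit design's expected average depth falls
    below the threshold.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    truth = GroundTruth()
    rosters: dict[str, list[str]] = {}
    mafs: dict[str, list[MafRecord]] = {}
    designs = {k.kit_name: k for k in config.kits}
    for cohort in cohorts:
        if cohort.kit_name not in designs:
            raise ValueError(f"cohort {cohort.name}: no kit spec for {cohort.kit_name!r}")
    for gene in models:
        truth.true_rate[gene.gene_symbol] = config.rate_of(gene.gene_symbol)
    for cohort in cohorts:
        samples = [f"{cohort.name}-S{i + 1:04d}" for i in range(cohort.n_samples)]
        rosters[cohort.name] = samples
        records: list[MafRecord] = []
        truth.censored[cohort.name] = {}
        for gene in models:
            rate = config.rate_of(gene.gene_symbol)
            mutated = rng.random(cohort.n_samples) < rate
            if avg_depths is not None:
                avgs = np.asarray(avg_depths[cohort.name][gene.gene_symbol])
            else:
                avgs = _analytic_avg_depth(gene, cohort, config, rng)
            expected = float(np.mean(avgs))
            if config.censor_rule == "step_at_min_avg_depth":
                emitted = mutated & (avgs >= config.min_avg_depth)
            else:
                emitted = mutated
            truth.censored[cohort.name][gene.gene_symbol] = bool(
                config.censor_rule == "step_at_min_avg_depth"
                and expected < config.min_avg_depth
            )
            for i in np.flatnonzero(emitted):
                records.append(
                    MafRecord(
                        gene.gene_symbol,
                        _NONSILENT[int(rng.integers(len(_NONSILENT)))],
                        samples[int(i)],
                        cohort.name,
                    )
                )
        mafs[cohort.name] = records
    return mafs, rosters, truth


def _analytic_avg_depth(
    gene: GeneModel,
    cohort: CohortSpec,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Average region depth per sample without materialising the base matrix.

    Only meaningful when the caller has no planted design (fully covered
    world): the per-sample total of independent Poisson base counts is
    Poisson with the summed mean. For the negative binomial the per-base
    draws are materialised instead.
    """
    L = gene.region_length(config.region_mode) or gene.exon_length
    if config.depth_model == "poisson":
        return rng.poisson(lam=config.mean_on * L, size=cohort.n_samples) / L
    mean_vec = np.full(L, config.mean_on)
    mat = _draw_depth(mean_vec, (cohort.n_samples, L), config, rng)
    return mat.mean(axis=1)


def simulate_bundle(
    config: SimulationConfig,
    outdir: str | Path | None = None,
    include_depth: bool = False,
) -> SyntheticBundle:
    """Run the whole stated world once, memory-bounded, and collect outputs.

    Per cohort × gene the per-base depth matrix is drawn, reduced to
    per-sample averages (feeding sufficiency and MAF censoring) and the
    cross-sample mean profile (feeding the depth-based undercoverage audit),
    then discarded. One seed drives genome, designs, depth and mutations.
    """
    rng = np.random.default_rng(config.seed)
    models = make_genome(config, rng)
    designs: dict[str, CaptureDesign] = {}
    truth = GroundTruth()
    for kit_spec in config.kits:
        design, kit_truth = make_design(models, kit_spec, rng, config.region_mode)
        designs[kit_spec.kit_name] = design
        truth.absent.update(kit_truth.absent)
        truth.partial.update(kit_truth.partial)
        truth.design_fraction.update(kit_truth.design_fraction)
    for gene in models:
        truth.true_rate[gene.gene_symbol] = config.rate_of(gene.gene_symbol)

    rosters: dict[str, list[str]] = {}
    kit_assignments: list[KitAssignment] = []
    coverage: list[SampleCoverage] = []
    mean_profiles: dict[tuple[str, str], np.ndarray] = {}
    avg_depths: dict[str, dict[str, np.ndarray]] = {}
    for cohort in config.cohorts:
        samples = [f"{cohort.name}-S{i + 1:04d}" for i in range(cohort.n_samples)]
        rosters[cohort.name] = samples
        kit_assignments.extend(
            KitAssignment(sid, cohort.name, cohort.kit_name) for sid in samples
        )
        design = designs[cohort.kit_name]
        avg_depths[cohort.name] = {}
        for gene in models:
            mask = _coverage_mask(gene, design, config.region_mode)
            mean_vec = np.where(mask, config.mean_on, config.mean_off)
            mat = _draw_depth(mean_vec, (cohort.n_samples, mask.size), config, rng)
            avgs = mat.mean(axis=1)
            mean_profiles[(cohort.name, gene.gene_symbol)] = mat.mean(axis=0)
            avg_depths[cohort.name][gene.gene_symbol] = avgs
            L = mask.size
            for sid, avg in zip(samples, avgs):
                coverage.append(
                    SampleCoverage(
                        sample_id=sid,
                        gene_symbol=gene.gene_symbol,
                        read_count=int(round(avg * L / config.read_length)),
                        avg_exon_coverage=float(avg),
                        sufficient=bool(avg >= config.min_avg_depth),
                        cohort_id=cohort.name,
                        kit_name=cohort.kit_name,
                    )
                )

    mafs, _, maf_truth = simulate_maf(models, config.cohorts, config, avg_depths, rng)
    truth.censored = maf_truth.censored
    bundle = SyntheticBundle(
        config,
        models,
        designs,
        rosters,
        kit_assignments,
        mafs,
        coverage,
        mean_profiles,
        truth,
    )
    if outdir is not None:
        bundle.write(outdir, include_depth=include_depth)
    return bundle


# ---------------------------------------------------------------------------
# Synthetic SAM emitter (exercises the alignment-filtering code paths)


def simulate_sam(
    path: str | Path,
    gene: GeneModel,
    n_reads: int,
    rng: np.random.Generator | int | None = None,
    read_length: int = 100,
    frac_duplicate: float = 0.1,
    frac_low_mapq: float = 0.1,
    mapq_pass: int = 60,
    mapq_fail: int = 10,
) -> dict:
    """Write a small SAM file of fully-matching reads over a gene's exons.

    A configurable share of reads is duplicate-flagged or assigned MAPQ below
    the audit threshold, so filtering attrition is known by construction.
    Returns the planted counts per category.
    """
    import pysam

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    path = Path(path)
    ref_len = gene.exons[-1].end + read_length + 1
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": gene.chrom, "LN": ref_len}],
    }
    exon_starts = np.array([iv.start for iv in gene.exons])
    exon_lens = np.array([len(iv) for iv in gene.exons])
    planted = {"kept": 0, "duplicate": 0, "low_mapq": 0}
    entries = []
    for i in range(n_reads):
        e = int(rng.integers(len(exon_starts)))
        offset = int(rng.integers(max(exon_lens[e], 1)))
        start = int(exon_starts[e] + offset)
        u = rng.random()
        if u < frac_duplicate:
            flag, mapq, cat = 1024, mapq_pass, "duplicate"
        elif u < frac_duplicate + frac_low_mapq:
            flag, mapq, cat = 0, mapq_fail, "low_mapq"
        else:
            flag, mapq, cat = 0, mapq_pass, "kept"
        planted[cat] += 1
        entries.append((start, f"read{i:05d}", flag, mapq))
    entries.sort()
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for start, name, flag, mapq in entries:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.flag = flag
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = mapq
            a.cigarstring = f"{read_length}M"
            a.query_sequence = "A" * read_length
            a.query_qualities = pysam.qualitystring_to_array("I" * read_length)
            out.write(a)
    return planted
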