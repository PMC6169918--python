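# Methods

## The audit model

Whole-exome sequencing reads only what the capture kit's probes hybridize.
The audit treats a cohort's lack of called mutations in a gene as a
three-part question: (i) is the absence statistically surprising given the
gene's mutation rate elsewhere, (ii) is per-sample read depth at the locus
sufficient for the caller to have seen a mutation, and (iii) does the
insufficiency segregate with the capture kit the samples were sequenced with?

### Screening rule

For gene *g* over cohorts *c* with roster sizes *n_c* and mutated-sample
counts *m_c(g)* (non-silent calls, each sample counted once):

- pooled rate: `r(g) = Σ m_c(g) / Σ n_c` over cohorts with `m_c(g) ≥ 1`;
- candidate iff `r(g) ≥ min_rate` (default 0.05) **and** the number of
  cohorts with `m_c(g) = 0` is ≥ `min_zero_cohorts` (default 3).

The rate restriction to non-zero cohorts avoids diluting a gene's prevalence
with exactly the cohorts under suspicion; the cohort-count floor discards
absences that small cohorts produce by chance even at a 5% true rate. The
"rate across non-zero cohorts" wording is ambiguous between pooling samples
and averaging per-cohort rates; pooling (the stricter-denominator reading)
is the default and `rate_method="mean"` is exposed. Non-silent is the fixed
term set {Missense, Nonsense, Nonstop, Frame_Shift_Ins/Del, In_Frame_Ins/Del,
Splice_Site, Translation_Start_Site}; unrecognized terms are logged and
treated as silent so malformed rows can never create a call.

### Coverage sufficiency

Reads are filtered before any depth computation: duplicate-flagged reads and
reads with MAPQ strictly below 30 are discarded (MAPQ = 30 is kept);
unmapped, secondary and supplementary records are also excluded — the latter
two go beyond the minimal duplicate/MAPQ rule but prevent double-counting
and are logged. Depth at a base counts reference-consuming aligned segments
(CIGAR M/=/X); deletions and skips contribute nothing; overlapping mates
double-count (no mate-clipping rule is modelled, stated explicitly).

Thresholds, with boundary semantics fixed once in `AuditThresholds`:

| parameter | default | semantics |
|---|---|---|
| `min_mapq` | 30 | reads `< 30` discarded |
| `min_avg_depth` | 25x | sample sufficient iff mean exon depth `≥ 25` (a "minimum threshold" read inclusively) |
| `cohort_insufficiency_frac` | 0.75 | cohort undercovered iff insufficient fraction `> 0.75` (strict: "over 75%") |
| `base_depth_gt` | 20 | base qualifies iff cross-sample mean depth `> 20` (strict) |
| `qualifying_frac` | 0.80 | gene/exon covered iff qualifying fraction `≥ 0.80` ("fewer than 80%" ⇒ undercovered) |

The 25x sufficiency level corresponds to near-unit caller sensitivity for a
clonal heterozygous mutation at the tumor purity typical of curated cohorts.
Gene status is three-valued: `covered`; `undercovered_incomplete`
(0 < fraction < 0.8, partial probe tiling); `undercovered_absent`
(fraction exactly 0, no probes at the locus). The per-exon rule applies the
same fraction test per exon to the cross-sample mean profile — whether the
original per-exon analysis used cross-sample means or per-sample depth is
not stated; the cross-sample mean is used for consistency with the gene rule.

### Design-based audit

When a kit's target BED is public the same taxonomy is computed from
geometry alone: `covered_fraction = |region ∩ targets| / |region|` in exon
or CDS mode. Non-coding genes cannot be scored in CDS mode; they are
excluded and counted in the summary rather than scored 0, since published
exon-vs-CDS undercovered counts imply different denominators without
spelling them out. No probe padding is applied by default (real capture
recovers some flanking bases; a configurable `pad` is exposed, default 0).
Intervals are uniformly 0-based half-open internally; 1-based dialects
convert on read; touching intervals merge (probe adjacency is irrelevant to
base counting); strand is carried but ignored by all coverage math.
Duplicate gene symbols in annotation input are an error — the audit assumes
one canonical transcript per gene and will not silently resolve ties, which
also surfaces same-symbol genes on different chromosomes.

### Kit attribution

`kit_explains(gene, cohort, kit)` returns two set statements: every
insufficient sample uses the kit; every kit user is insufficient. Together
they state that kit usage exactly delineates insufficiency in the cohort.
Samples without kit metadata form an `Unknown` stratum rather than being
dropped, so per-cohort sample counts are conserved across kit strata. The
Fisher exact test with Benjamini–Hochberg adjustment across genes is an
optional extension (off by default): the audit's claims are tabulations, not
hypothesis tests.

## The synthetic world

The generator emulates the structures the audit runs on, with one seed
driving everything (genome, designs, depth, mutations; emitted files are
byte-identical across runs):

- **genome** — non-overlapping genes on synthetic chromosomes; total exon
  content uniform in 500–3000 bp (the scale of typical canonical coding
  genes; the sources state no value, chosen once), 1–6 exons, 10% of exon
  bases trimmed from each end as UTR; optional non-coding fraction.
- **designs** — per kit: a configured fraction of genes gets no probes, a
  fraction gets a contiguous tiling of a uniform-random 30–70% of region
  bases (centred on "incomplete", away from both the 0 and 0.8 status
  boundaries, and never depth-censorable at 100x on-probe depth), the rest
  are tiled exactly.
- **depth** — per base, independent Poisson (default) or negative-binomial
  (`var = m + a·m²`) counts with mean 100x on-probe (the typical exome
  average) and 0.5x off-probe.
- **mutations** — each sample × gene mutates at its true rate (default 10%);
  under the step rule a call reaches the MAF only when the sample's average
  region depth is ≥ 25x, mirroring the sufficiency rule. The censoring
  ground truth is deterministic (expected average depth below 25x), so
  recovery checks compare against planted, not sampled, labels. A logistic
  sensitivity curve would be more faithful to a real caller near the
  threshold; the step rule is used because at 100x-vs-0.5x the per-sample
  averages sit far from 25x and the two coincide.

What a green planted-truth test establishes: the pipeline's rules compose
correctly — genes censored by the planted kit are recovered by the screen
with no false positives among covered genes, their cohorts are called
undercovered, BED-based and depth-based statuses agree, and kit attribution
flags the defective kit. What it does not establish: behaviour on real data
with GC-dependent capture efficiency, correlated depth along the genome,
mate-pair overlap, subclonal variants near the caller's sensitivity limit,
or annotation mismatches — none of which the generator models.

Depth is simulated per base rather than via reads, for speed; a small SAM
emitter with planted duplicate/low-MAPQ fractions exercises the alignment
filtering and pileup code paths separately.

## Verification scope

The acceptance suite checks (a) the cohort-summary code paths on synthetic
stand-in tables constructed to match published reference marginals (441
samples with 425 below 1,000 filtered reads, median 12, maximum average
exon coverage 6.4 over a 21,470-base exon set and none sufficient at 25x; a
512-vs-10 mixed-kit cohort split; a 120-sample kit-explained cohort) — the
stand-ins verify the summarisation logic, not agreement with the original
controlled-access data; (b) exact equivalence of all interval arithmetic
with per-base brute force on 1,000 random instances; (c) 20-seed
planted-truth recovery of the full pipeline at the reference scale; and
(d) threshold-monotonicity and conservation invariants (stricter thresholds
never shrink the undercovered set; kit strata conserve cohort counts;
gene-level covered fraction equals the exon-length-weighted mean of per-exon
fractions). Re-running full published genome-scale counts requires the
manufacturer BEDs, annotation snapshots and cohort MAFs as inputs; the
readers accept exactly those formats but the files are not redistributable
here.

## Numerical and degenerate-input choices

- Empty interval lists intersect to 0; empty BED files parse to an empty
  design with a warning; a BED record with `start ≥ end` is an error naming
  the line.
- `mean_depth_profile` requires identical gene/mode/length across samples;
  cross-sample means are plain arithmetic means, not depth-normalized.
- CDS-mode depth tracks on non-coding genes are an error (callers skip and
  report), mirroring the design-audit exclusion.
- Samples appearing in a MAF but missing from the roster are added with a
  warning (conservative denominators); rosters are always supplied
  explicitly because fully uncalled samples would otherwise vanish from
  denominators.
- `read_depth_tsv` treats absent positions as depth 0, skips (and counts)
  positions outside every gene region, and rejects duplicated positions.
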