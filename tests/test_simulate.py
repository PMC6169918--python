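"""Synthetic-world generator: determinism, planted structure, calibration."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from capaudit.design import audit_design, covered_fraction
from capaudit.intervals import total_length
from capaudit.simulate import (
    CohortSpec,
    GroundTruth,
    KitSpec,
    SimulationConfig,
    make_design,
    make_genome,
    simulate_bundle,
    simulate_depth,
    simulate_maf,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mean_on": 5, "mean_off": 10},
            {"depth_model": "zipf"},
            {"censor_rule": "sigmoid"},
            {"n_genes": 0},
            {"depth_model": "negative_binomial", "dispersion": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_cohort_with_unknown_kit_rejected(self):
        with pytest.raises(ValueError, match="unknown kit"):
            SimulationConfig(cohorts=[CohortSpec("C", 5, "nokit")])

    def test_kit_spec_fraction_bounds(self):
        with pytest.raises(ValueError):
            KitSpec("k", absent_frac=0.7, partial_frac=0.5)


class TestMakeGenome:
    def test_deterministic_under_seed(self, small_config):
        m1 = make_genome(small_config)
        m2 = make_genome(small_config)
        assert m1 == m2

    def test_exon_lengths_within_configured_range(self, small_config):
        for m in make_genome(small_config):
            lo, hi = small_config.gene_length_range
            assert lo <= m.exon_length <= hi
            elo, ehi = small_config.exons_per_gene_range
            assert elo <= len(m.exons) <= ehi

    def test_single_exon_config(self, small_config):
        cfg = replace(small_config, exons_per_gene_range=(1, 1))
        assert all(len(m.exons) == 1 for m in make_genome(cfg))

    def test_genes_do_not_overlap(self, small_config):
        models = make_genome(small_config)
        by_chrom: dict = {}
        for m in models:
            by_chrom.setdefault(m.chrom, []).append(m)
        for ms in by_chrom.values():
            ms.sort(key=lambda m: m.exons[0].start)
            for a, b in zip(ms, ms[1:]):
                assert a.exons[-1].end < b.exons[0].start

    def test_noncoding_fraction(self, small_config):
        cfg = replace(small_config, noncoding_frac=1.0)
        assert all(m.cds == () for m in make_genome(cfg))
        assert all(m.cds for m in make_genome(small_config))


class TestMakeDesign:
    def test_absent_frac_one_empties_design(self, small_config):
        models = make_genome(small_config)
        design, truth = make_design(models, KitSpec("k", absent_frac=1.0), 1)
        assert design.total_target_bases == 0
        assert len(truth.absent["k"]) == len(models)

    def test_all_covered_when_no_defects(self, small_config):
        models = make_genome(small_config)
        design, _ = make_design(models, KitSpec("k"), 1)
        rows, summary = audit_design(design, models)
        assert summary["n_undercovered"] == 0

    def test_planted_partial_fraction_recovered_by_audit(self, small_config):
        models = make_genome(small_config)
        spec = KitSpec("k", partial_frac=0.5, partial_range=(0.3, 0.7))
        design, truth = make_design(models, spec, 2)
        by_symbol = {m.gene_symbol: m for m in models}
        for g, planted in truth.partial["k"].items():
            frac = covered_fraction(by_symbol[g], design)
            L = by_symbol[g].exon_length
            assert abs(frac - planted) <= 1.0 / L  # one base of rounding
            assert frac == pytest.approx(truth.design_fraction["k"][g])

    def test_ground_truth_statuses(self, small_config):
        models = make_genome(small_config)
        spec = KitSpec("k", absent_frac=0.2, partial_frac=0.2)
        design, truth = make_design(models, spec, 3)
        rows, _ = audit_design(design, models)
        for r in rows:
            assert r.status == truth.design_status("k", r.gene_symbol)


class TestSimulateDepth:
    def test_absent_gene_all_zero_when_mean_off_zero(self, small_config):
        cfg = replace(small_config, mean_off=0.0)
        models = make_genome(cfg)[:5]
        design, _ = make_design(models, KitSpec("k", absent_frac=1.0), 0)
        tracks = simulate_depth(models, design, 3, cfg, 0)
        for per_gene in tracks.values():
            for t in per_gene.values():
                assert t.depths.sum() == 0

    def test_fully_covered_gene_qualifies_at_100x(self, small_config):
        models = make_genome(small_config)[:5]
        design, _ = make_design(models, KitSpec("k"), 0)
        tracks = simulate_depth(models, design, 20, small_config, 0)
        from capaudit.coverage import call_undercovered_gene, mean_depth_profile

        for m in models:
            profile = mean_depth_profile([tracks[s][m.gene_symbol] for s in tracks])
            call = call_undercovered_gene(profile, m.gene_symbol)
            assert call.status == "covered"
            assert call.qualifying_fraction == pytest.approx(1.0)

    def test_same_seed_identical_tracks(self, small_config):
        models = make_genome(small_config)[:3]
        design, _ = make_design(models, KitSpec("k"), 0)
        t1 = simulate_depth(models, design, 4, small_config, 42)
        t2 = simulate_depth(models, design, 4, small_config, 42)
        for sid in t1:
            for g in t1[sid]:
                assert np.array_equal(t1[sid][g].depths, t2[sid][g].depths)

    def test_negative_binomial_matches_mean(self, small_config):
        cfg = replace(small_config, depth_model="negative_binomial", dispersion=0.2)
        models = make_genome(cfg)[:2]
        design, _ = make_design(models, KitSpec("k"), 0)
        tracks = simulate_depth(models, design, 50, cfg, 5)
        all_depths = np.concatenate(
            [t.depths for per_gene in tracks.values() for t in per_gene.values()]
        )
        assert np.mean(all_depths) == pytest.approx(cfg.mean_on, rel=0.05)
        # overdispersed relative to Poisson
        assert np.var(all_depths) > 1.5 * np.mean(all_depths)


class TestSimulateMaf:
    def test_zero_rate_empty_maf_full_rosters(self, small_config):
        cfg = replace(small_config, mutation_rate=0.0)
        models = make_genome(cfg)[:5]
        mafs, rosters, _ = simulate_maf(models, cfg.cohorts, cfg, rng=0)
        assert all(len(v) == 0 for v in mafs.values())
        assert all(len(rosters[c.name]) == c.n_samples for c in cfg.cohorts)

    def test_uncensored_rates_within_exact_binomial_99ci(self):
        """With censoring off, observed cohort rates match true rates."""
        cfg = SimulationConfig(
            n_genes=10,
            gene_length_range=(200, 400),
            cohorts=[CohortSpec("C1", 500, "kit_complete")],
            kits=[KitSpec("kit_complete")],
            censor_rule="none",
            mutation_rate=0.10,
            seed=3,
        )
        models = make_genome(cfg)
        mafs, rosters, _ = simulate_maf(models, cfg.cohorts, cfg, rng=3)
        n = 500
        lo = stats.binom.ppf(0.005, n, 0.10)
        hi = stats.binom.ppf(0.995, n, 0.10)
        for m in models:
            k = len({r.sample_id for r in mafs["C1"] if r.gene_symbol == m.gene_symbol})
            assert lo <= k <= hi, (m.gene_symbol, k)

    def test_step_censoring_ground_truth(self, small_config):
        bundle = simulate_bundle(small_config)
        truth = bundle.truth
        # absent genes on the biased kit are censored in exactly its cohorts
        biased_cohorts = {c.name for c in small_config.cohorts if c.kit_name == "kit_biased"}
        for g in truth.absent["kit_biased"]:
            for cohort, per_gene in truth.censored.items():
                assert per_gene[g] == (cohort in biased_cohorts)
        # and emitted MAFs contain no calls in censored cells
        for cohort, records in bundle.maf_records.items():
            called = {r.gene_symbol for r in records}
            for g, censored in truth.censored[cohort].items():
                if censored:
                    assert g not in called


class TestBundleDeterminism:
    def test_same_seed_byte_identical_files(self, small_config, tmp_path):
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        simulate_bundle(small_config, d1)
        simulate_bundle(small_config, d2)
        files1 = sorted(p.name for p in d1.iterdir())
        assert files1 == sorted(p.name for p in d2.iterdir())
        for name in files1:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_ground_truth_json_round_trip(self, small_config, tmp_path):
        bundle = simulate_bundle(small_config)
        p = tmp_path / "truth.json"
        bundle.truth.to_json(p)
        back = GroundTruth.from_json(p)
        assert back.absent == bundle.truth.absent
        assert back.censored == bundle.truth.censored

    def test_coverage_rows_conserved(self, small_config):
        bundle = simulate_bundle(small_config)
        n_expected = sum(c.n_samples for c in small_config.cohorts) * len(bundle.models)
        assert len(bundle.coverage) == n_expected
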