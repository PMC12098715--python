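"""Generator properties: reproducibility, class allocation, planted effects."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from frogclock.synthdata import (
    SynthConfig,
    generate_cohort,
    generate_context_fixtures,
    generate_methylation,
)


class TestGenerateCohort:
    def test_fixed_seed_reproducible(self, small_config):
        a = generate_cohort(small_config)
        b = generate_cohort(small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_one_age_and_strain_per_tank(self, small_cohort):
        samples, _, _ = small_cohort
        per_tank = samples.groupby("tank_id")[["age_years", "strain"]].nunique()
        assert (per_tank == 1).all().all()

    def test_single_tank_shares_everything(self):
        cfg = SynthConfig(n_tanks=1, frogs_per_tank=3, seed=5)
        s = generate_cohort(cfg)
        assert len(s) == 3
        assert s["tank_id"].nunique() == 1
        assert s["age_years"].nunique() == 1

    def test_study_scale_tank_structure(self):
        cfg = SynthConfig(n_tanks=34, frogs_per_tank=6, seed=7)
        s = generate_cohort(cfg)
        sizes = s.groupby("tank_id").size()
        assert len(sizes) == 34
        assert sizes.median() == 6

    def test_ages_within_range(self, small_cohort, small_config):
        samples, _, _ = small_cohort
        lo, hi = small_config.age_range
        assert samples["age_years"].between(lo, hi).all()

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"n_tanks": 0}, "n_tanks"),
            ({"age_range": (0.0, 5.0)}, "age_range"),
            ({"frac_pos": 0.6, "frac_neg": 0.5}, "frac_pos"),
            ({"precision": -1.0}, "precision"),
            ({"t_allele_freq": 1.5}, "t_allele_freq"),
            ({"frogs_per_tank": (3, 3)}, "frogs_per_tank"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            generate_cohort(SynthConfig(**kwargs))


class TestGenerateMethylation:
    def test_fixed_seed_byte_identical(self, small_config, small_cohort):
        samples, matrix, truth = small_cohort
        m2, t2 = generate_methylation(samples, small_config)
        pd.testing.assert_frame_equal(matrix.beta, m2.beta)
        pd.testing.assert_frame_equal(matrix.coverage, m2.coverage)
        pd.testing.assert_series_equal(truth.site_class, t2.site_class)

    def test_exact_class_allocation(self):
        cfg = SynthConfig(n_tanks=4, frogs_per_tank=3, n_sites=1000,
                          frac_artifact=0.1, seed=3)
        s = generate_cohort(cfg)
        _, truth = generate_methylation(s, cfg)
        assert (truth.site_class == "artifact").sum() == 100

    def test_tt_genotype_below_cutoff(self, small_cohort):
        _, matrix, truth = small_cohort
        for site in truth.genotype.index:
            tt = truth.genotype.loc[site] == "TT"
            if tt.any():
                assert (matrix.beta.loc[site, tt.index[tt]] < 0.006).all()

    def test_genotype_only_for_artifact_sites(self, small_cohort):
        _, _, truth = small_cohort
        assert set(truth.genotype.index) == set(
            truth.site_class.index[truth.site_class == "artifact"]
        )

    def test_positive_slope_sites_correlate_positively(self):
        # 1000 replicate positive-trend sites at slope_scale 0.2/yr, phi=50:
        # the per-site Spearman sign should essentially never flip at n=60.
        cfg = SynthConfig(n_tanks=10, frogs_per_tank=6, n_sites=1000,
                          frac_pos=1.0, frac_neg=0.0, frac_artifact=0.0, seed=9)
        s = generate_cohort(cfg)
        m, truth = generate_methylation(s, cfg)
        ages = s["age_years"].to_numpy()
        r = np.array([spearmanr(row, ages).statistic for row in m.beta.to_numpy()])
        assert (r > 0).mean() >= 0.999

    def test_null_sites_uncorrelated_on_average(self):
        cfg = SynthConfig(n_tanks=10, frogs_per_tank=6, n_sites=1000,
                          frac_pos=0.0, frac_neg=0.0, frac_artifact=0.0, seed=13)
        s = generate_cohort(cfg)
        m, _ = generate_methylation(s, cfg)
        ages = s["age_years"].to_numpy()
        r = np.array([spearmanr(row, ages).statistic for row in m.beta.to_numpy()])
        assert abs(r.mean()) < 0.02

    def test_coverage_floored(self, small_cohort, small_config):
        _, matrix, _ = small_cohort
        assert (matrix.coverage.to_numpy() >= small_config.min_coverage).all()

    def test_empty_samples_rejected(self, small_config):
        with pytest.raises(ValueError):
            generate_methylation(pd.DataFrame(columns=["sample_id"]), small_config)


class TestContextFixtures:
    def test_every_site_in_exactly_one_interval(self, small_cohort, small_context):
        _, matrix, _ = small_cohort
        iv = small_context.segmentation.intervals
        for c, p in zip(matrix.chrom, matrix.pos):
            hits = iv[(iv["chrom"] == c) & (iv["start"] <= p) & (p < iv["end"])]
            assert len(hits) == 1

    def test_planted_enrichment_counts(self, small_cohort, small_context, small_config):
        _, _, truth = small_cohort
        state = small_context.site_state
        pos = truth.site_class == "positive"
        in_state = state == small_config.enriched_state
        frac_pos_in = (pos & in_state).sum() / pos.sum()
        frac_bg_in = in_state.mean()
        planted = np.log2(frac_pos_in / frac_bg_in)
        assert planted == pytest.approx(np.log2(0.5 / 0.1), abs=0.15)

    def test_null_design_states_independent_of_class(self, small_config, small_cohort):
        from dataclasses import replace

        _, matrix, truth = small_cohort
        cfg = replace(small_config, plant_effects=False)
        ctx = generate_context_fixtures(matrix, truth, cfg)
        pos = truth.site_class == "positive"
        rate_pos = (ctx.site_state[pos] == cfg.enriched_state).mean()
        rate_all = (ctx.site_state == cfg.enriched_state).mean()
        assert abs(rate_pos - rate_all) < 0.15

    def test_homolog_map_unique_gene_ids(self, small_context):
        hm = small_context.homolog_map
        assert not hm["gene_id"].duplicated().any()
        assert set(small_context.annotation.genes["gene_id"]) == set(hm["gene_id"])

    def test_planted_genes_within_5kb_of_positive_sites(
        self, small_cohort, small_context
    ):
        _, matrix, truth = small_cohort
        pos_sites = truth.site_class.index[truth.site_class == "positive"]
        planted_raw = {g.removeprefix("XL-") for g in small_context.planted_genes}
        genes = small_context.annotation.genes
        planted = genes[genes["gene_id"].isin(planted_raw)]
        site_pos = {
            (c, p)
            for c, p in zip(matrix.chrom, matrix.pos)
        }
        pos_lookup = pd.DataFrame(
            {"chrom": matrix.chrom, "pos": matrix.pos}, index=matrix.site_ids
        ).loc[pos_sites]
        for _, row in planted.iterrows():
            near = pos_lookup[
                (pos_lookup["chrom"] == row["chrom"])
                & ((pos_lookup["pos"] - row["tss_pos"]).abs() <= 5000)
            ]
            assert len(near) >= 1
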