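"""Generator contracts: determinism, variance decomposition, planted structure."""

import numpy as np
import pandas as pd
import pytest

from conftest import small_generator_config
from toxpod.study import effect_table, filter_studies, write_registry
from toxpod.synthetic import (
    BlockSpec,
    ConfigurationError,
    GeneratorConfig,
    generate_descriptors,
    generate_registry,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [("sd_chemical", -0.1), ("n_chemicals", 1), ("frac_in_range", 1.5)],
    )
    def test_invalid_field_named_in_error(self, field, value):
        cfg = GeneratorConfig(**{field: value})
        with pytest.raises(ConfigurationError, match=field):
            cfg.validate()

    def test_default_variances_compose_to_reference_total(self):
        cfg = GeneratorConfig()
        total = np.sqrt(cfg.sd_covariate**2 + cfg.sd_chemical**2 + cfg.sd_study**2)
        assert total == pytest.approx(0.94, abs=0.01)

    def test_more_chemicals_than_studies_rejected(self):
        cfg = GeneratorConfig(n_chemicals=100, studies_per_source={"TOXREF": 10, "HESS": 5, "COSMOS": 5})
        with pytest.raises(ConfigurationError):
            cfg.validate()


class TestRegistryGeneration:
    def test_degenerate_variances_collapse_to_source_means(self):
        cfg = small_generator_config()
        cfg.sd_covariate = cfg.sd_chemical = cfg.sd_study = 0.0
        cfg.frac_in_range = 1.0  # disable deliberate censoring to isolate the mechanism
        records, _ = generate_registry(cfg)
        eff = effect_table(filter_studies(records))
        for src, mean in cfg.source_means.items():
            vals = eff.loc[eff.source == src, "value_log10"]
            np.testing.assert_allclose(vals, mean, atol=1e-9)

    def test_same_seed_byte_identical_registry(self, tmp_path):
        cfg = small_generator_config(seed=13)
        r1, t1 = generate_registry(cfg)
        r2, t2 = generate_registry(small_generator_config(seed=13))
        assert t1 == t2
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_registry(r1, p1)
        write_registry(r2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_counts_and_sources(self, small_config, small_registry):
        records, truth = small_registry
        assert len(records) == sum(small_config.studies_per_source.values())
        assert len(truth) == small_config.n_chemicals
        per_source = pd.Series([r.source for r in records]).value_counts().to_dict()
        assert per_source == small_config.studies_per_source
        assert len({r.chemical_id for r in records}) == small_config.n_chemicals

    def test_default_scale_sample_sd_recovers_total(self):
        # Monte Carlo over 3 seeds at the full default scale (~4379 studies)
        sds, means = [], []
        for seed in (101, 102, 103):
            records, _ = generate_registry(GeneratorConfig(seed=seed))
            eff = effect_table(filter_studies(records))
            assert len(eff) == 4379
            sds.append(eff.value_log10.std(ddof=0))
            means.append(eff.value_log10.mean())
        assert np.mean(sds) == pytest.approx(0.94, abs=0.05)
        assert np.mean(means) == pytest.approx(1.7, abs=0.05)

    def test_variance_components_recovered_by_anova(self):
        # between-chemical variance of ground truth vs configured sd_chemical
        cfg = GeneratorConfig(seed=5)
        records, truth = generate_registry(cfg)
        vals = np.array(list(truth.values()))
        assert vals.std() == pytest.approx(cfg.sd_chemical, abs=0.05)
        # residual SD within chemical after removing truth + source mean
        eff = effect_table(filter_studies(records))
        eff = eff[eff.qualifier == "="]  # censored rows shift the residual
        resid = (
            eff.value_log10
            - eff.chemical_id.map(truth)
            - eff.source.map(cfg.source_means)
        )
        expected = np.sqrt(cfg.sd_covariate**2 + cfg.sd_study**2)
        assert resid.std() == pytest.approx(expected, abs=0.05)


class TestDescriptorGeneration:
    def test_zero_signal_fraction_gives_null_correlations(self):
        cfg = small_generator_config()
        cfg.descriptor_block_specs = {
            "physchem": BlockSpec(10, 0.0, missing_rate=0.0)
        }
        records, truth = generate_registry(cfg)
        blocks = generate_descriptors(sorted(truth), truth, cfg)
        X = blocks["physchem"].data
        z = pd.Series(truth).loc[X.index]
        corrs = X.corrwith(z).abs()
        assert (corrs < 0.25).all()

    def test_signal_features_track_chemical_effect(self, small_blocks, small_registry):
        _, truth = small_registry
        X = small_blocks["physchem"].data
        z = pd.Series(truth).loc[X.index]
        # half the physchem block is informative by construction
        strong = (X.corrwith(z).abs() > 0.25).sum()
        assert strong >= 4

    def test_planted_duplicate_pair_has_unit_correlation(self, small_blocks):
        X = small_blocks["padel"].data
        dup = [c for c in X.columns if "dup" in c]
        assert dup
        for c in dup:
            partners = X.corrwith(X[c]).drop(index=c).abs()
            assert partners.max() == pytest.approx(1.0)

    def test_missing_cell_count_within_binomial_bounds(self):
        cfg = small_generator_config()
        cfg.n_chemicals = 1000
        cfg.studies_per_source = {"TOXREF": 700, "HESS": 310, "COSMOS": 120}
        cfg.descriptor_block_specs = {"padel": BlockSpec(100, 0.2, missing_rate=0.1)}
        records, truth = generate_registry(cfg)
        blocks = generate_descriptors(sorted(truth), truth, cfg)
        n_cells = blocks["padel"].data.size
        n_missing = int(blocks["padel"].data.isna().sum().sum())
        expect = 0.1 * n_cells
        sigma = np.sqrt(n_cells * 0.1 * 0.9)
        assert abs(n_missing - expect) < 3 * sigma

    def test_unknown_block_kind_rejected(self, small_registry):
        cfg = small_generator_config()
        cfg.descriptor_block_specs = {"mystery": BlockSpec(5, 0.1, kind="fractal")}
        _, truth = small_registry
        with pytest.raises(ConfigurationError, match="mystery"):
            generate_descriptors(sorted(truth), truth, cfg)

    def test_block_availability_nested(self, small_blocks):
        httk = set(small_blocks["httk"].data.index)
        tox = set(small_blocks["toxcast"].chemicals)
        assert httk <= tox

    def test_same_seed_identical_descriptors(self, small_registry):
        cfg = small_generator_config()
        _, truth = small_registry
        a = generate_descriptors(sorted(truth), truth, cfg)
        b = generate_descriptors(sorted(truth), truth, cfg)
        pd.testing.assert_frame_equal(a["physchem"].data, b["physchem"].data)
        pd.testing.assert_frame_equal(a["toxcast"].ac50_um, b["toxcast"].ac50_um)
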