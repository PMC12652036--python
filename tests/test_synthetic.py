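import numpy as np
import pandas as pd
import pytest

from periomics.rmcorr import rmcorr
from periomics.synthetic import (
    CONDITIONS,
    AnalyteSpec,
    CohortConfig,
    ConfigurationError,
    TaxonSpec,
    default_taxa,
    generate_cohort,
)


class TestConfigValidation:
    def test_default_config_is_valid(self):
        CohortConfig().validate()

    def test_empty_visits_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(visits=()).validate()

    def test_zero_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(n_subjects_per_arm=(0, 10)).validate()

    def test_non_psd_loadings_rejected(self):
        bad = TaxonSpec("X_y", (1, 1, 1), 0.9, 0.5, loading=0.9, group="red",
                        group_loading=0.9)
        with pytest.raises(ConfigurationError, match="PSD"):
            bad.validate()

    def test_nonpositive_targets_rejected(self):
        with pytest.raises(ConfigurationError):
            AnalyteSpec("X", (0.0, 1.0, 2.0)).validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = CohortConfig(n_subjects_per_arm=(5, 6), seed=42)
        path = tmp_path / "cohort.yaml"
        cfg.to_yaml(path)
        back = CohortConfig.from_yaml(path)
        assert back.n_subjects_per_arm == (5, 6)
        assert back.seed == 42
        assert back.analytes["IL-1b"].targets == cfg.analytes["IL-1b"].targets


class TestDeterminism:
    def test_same_seed_identical_tables(self):
        cfg = dict(n_subjects_per_arm=(6, 6), seed=11, emit_site_curves=False)
        a = generate_cohort(CohortConfig(**cfg))
        b = generate_cohort(CohortConfig(**cfg))
        pd.testing.assert_frame_equal(a.metadata, b.metadata)
        pd.testing.assert_frame_equal(a.biomarkers, b.biomarkers)
        pd.testing.assert_frame_equal(a.abundance.relative, b.abundance.relative)
        pd.testing.assert_frame_equal(a.standards, b.standards)

    def test_different_seeds_differ(self):
        a = generate_cohort(CohortConfig(n_subjects_per_arm=(6, 6), seed=1,
                                         emit_site_curves=False))
        b = generate_cohort(CohortConfig(n_subjects_per_arm=(6, 6), seed=2,
                                         emit_site_curves=False))
        assert not np.allclose(
            a.biomarkers["IL-1b"].dropna(), b.biomarkers["IL-1b"].dropna()
        )


class TestStructure:
    def test_sequenced_sample_count(self, default_cohort):
        # 83 subjects x 3 pooled conditions x 2 sequenced visits
        assert default_cohort.abundance.relative.shape[1] == 498

    def test_biomarker_rows(self, default_cohort):
        # 83 subjects x 9 sites x 3 visits
        assert len(default_cohort.biomarkers) == 83 * 9 * 3

    def test_month6_carries_only_tlr(self, default_cohort):
        m6 = default_cohort.biomarkers.query("visit_month == 6")
        assert m6["TLR-ATP"].notna().all()
        assert m6["IL-1b"].isna().all()
        assert m6["GBI"].isna().all()

    def test_relative_abundance_sums_to_100(self, small_cohort):
        sums = small_cohort.abundance.relative.sum(axis=0)
        assert np.allclose(sums, 100.0)

    def test_community_has_513_species(self):
        assert len(default_taxa()) == 513

    def test_latent_severity_ordered_by_condition(self, default_cohort):
        sev = default_cohort.latent.query("visit_month == 0").groupby("condition")[
            "severity"
        ].mean()
        assert sev["healthy"] < sev["gingivitis"] < sev["periodontitis"]


class TestLargeSampleCalibration:
    def test_mean_matched_analytes_hit_targets_within_2pct(self, large_cohort):
        # law-of-large-numbers check over a fixed seed set: the mean across
        # three 1000-subject cohorts isolates bias from seed-level noise
        cohorts = [large_cohort] + [
            generate_cohort(
                CohortConfig(n_subjects_per_arm=(500, 500), seed=s,
                             emit_site_curves=False)
            )
            for s in (2, 3)
        ]
        bases = [c.biomarkers.query("visit_month == 0") for c in cohorts]
        for analyte in ("IL-1b", "MMP-9", "MMP-1", "gingipain", "MGI"):
            spec = cohorts[0].config.analytes[analyte]
            for cond, target in zip(CONDITIONS, spec.targets):
                got = np.mean(
                    [b.loc[b.condition == cond, analyte].mean() for b in bases]
                )
                assert got == pytest.approx(target, rel=0.02), (analyte, cond)

    def test_median_matched_analytes_hit_targets_within_10pct(self, large_cohort):
        base = large_cohort.biomarkers.query("visit_month == 0")
        for analyte in ("TLR-ATP", "TLR-SEAP"):
            spec = large_cohort.config.analytes[analyte]
            for cond, target in zip(CONDITIONS, spec.targets):
                got = base.loc[base.condition == cond, analyte].median()
                assert got == pytest.approx(target, rel=0.10), (analyte, cond)

    def test_condition_ordering_for_positive_loadings(self, large_cohort):
        base = large_cohort.biomarkers.query("visit_month == 0")
        for analyte in ("IL-1b", "endotoxin", "PAD", "MMP-9", "GBI", "MGI"):
            means = [
                base.loc[base.condition == c, analyte].mean() for c in CONDITIONS
            ]
            assert means[0] < means[1] < means[2], analyte

    def test_regimen_reduces_month24_biomarkers(self, large_cohort):
        m24 = large_cohort.biomarkers.query("visit_month == 24")
        for analyte in ("IL-1b", "MMP-1", "MMP-9", "GBI"):
            reg = m24.loc[m24.arm == "regimen", analyte].mean()
            ctrl = m24.loc[m24.arm == "control", analyte].mean()
            assert reg < ctrl, analyte

    def test_month24_arm_means_match_study_levels(self, large_cohort):
        m24 = large_cohort.biomarkers.query("visit_month == 24")
        targets = {"IL-1b": (115.90, 166.34), "MMP-1": (395.35, 519.71)}
        for analyte, (reg_t, ctrl_t) in targets.items():
            reg = m24.loc[m24.arm == "regimen", analyte].mean()
            ctrl = m24.loc[m24.arm == "control", analyte].mean()
            assert reg == pytest.approx(reg_t, rel=0.06), analyte
            assert ctrl == pytest.approx(ctrl_t, rel=0.06), analyte

    def test_zero_inflation_matches_configured_presence(self, large_cohort):
        rel = large_cohort.abundance.relative
        meta = large_cohort.metadata
        base = meta.query("visit_month == 0")
        spot = {t.name: t for t in large_cohort.config.taxa}
        checked = within2 = 0
        for name in list(spot)[30:90]:  # a band of fringe/filler taxa
            taxon = spot[name]
            for ci, cond in enumerate(CONDITIONS):
                cols = base.index[base.condition == cond]
                frac = (rel.loc[name, cols] > 0).mean()
                p = taxon.presence_by_condition()[ci]
                se = max(np.sqrt(p * (1 - p) / len(cols)), 1e-3)
                checked += 1
                within2 += abs(frac - p) <= 2 * se
                assert abs(frac - p) <= 5 * se, (name, cond)
        assert within2 / checked >= 0.90


class TestPairCalibration:
    def test_single_factor_loading_gives_squared_correlation(self):
        """With flat condition profiles and one shared factor of loading c,
        the within-subject correlation of two group members is c^2."""
        c = 0.9
        taxa = [
            TaxonSpec(f"Member_{i}", (0.2, 0.2, 0.2), 1.0, 0.6, 0.0, "red", c, "core")
            for i in range(2)
        ]
        taxa += [TaxonSpec("Filler_x", (0.2, 0.2, 0.2), 1.0, 0.6, 0.0, None, 0.0)]
        cfg = CohortConfig(
            n_subjects_per_arm=(250, 250),
            seed=5,
            taxa=taxa,
            taxa_treatment={},
            target_pairs=(),
            emit_site_curves=False,
        )
        co = generate_cohort(cfg)
        bio = co.abundance.to_biomass().absolute
        res = rmcorr(
            co.metadata["subject_id"].to_numpy(),
            bio.loc["Member_0"].to_numpy() ** 0.1,
            bio.loc["Member_1"].to_numpy() ** 0.1,
        )
        assert res.r == pytest.approx(c**2, abs=0.05)
        assert res.r >= 0.6

    def test_calibrated_pairs_recovered(self, large_cohort):
        co = large_cohort
        bio = co.biomarkers.dropna(subset=["IL-1b"])
        r = rmcorr(
            bio["subject_id"].to_numpy(),
            bio["IL-1b"].to_numpy() ** 0.1,
            bio["MMP-9"].to_numpy() ** 0.1,
        ).r
        assert r == pytest.approx(0.77, abs=0.05)

    def test_unreachable_pair_target_rejected(self):
        cfg = CohortConfig(target_pairs=(("IL-1b", "MMP-9", 0.9999),))
        with pytest.raises(ConfigurationError):
            generate_cohort(cfg)
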