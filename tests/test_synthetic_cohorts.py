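"""Generator contracts: cohort suite geometry, carrier genetics, twin
sharing, fracture risk model, amplicon geometry and phenotype IO."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from qrepbmd.adjustment import fit_all, zscores
from qrepbmd.synthetic_cohorts import (
    AlleleModel,
    StudySpec,
    default_study_suite,
    fracture_probability,
    read_phenotypes,
    records_to_frame,
    simulate_amplicon,
    simulate_cohort,
    write_phenotypes,
)


class TestStudySuite:
    def test_published_cohort_sizes_and_age_ranges(self):
        suite = {s.name: s for s in default_study_suite()}
        assert suite["TASOAC"].n_subjects == 385
        assert suite["TASOAC"].age_range == (50, 80)
        assert suite["Aberdeen"].n_subjects == 991
        assert suite["Aberdeen"].age_range == (45, 55)
        assert suite["Western Australian"].n_subjects == 1078
        assert suite["GOS random"].n_subjects == 822
        assert suite["GOS fracture"].n_subjects == 598
        assert suite["Sydney"].n_subjects == 980

    def test_volunteer_cohorts_total_3276(self):
        suite = {s.name: s for s in default_study_suite()}
        total = sum(
            suite[name].n_subjects
            for name in ("Western Australian", "GOS random", "TASOAC", "Aberdeen")
        )
        assert total == 3276

    def test_only_sydney_has_twins_and_only_wa_has_fracture(self):
        for s in default_study_suite():
            if s.name == "Sydney":
                assert s.twin_fraction > 0
            else:
                assert s.twin_fraction == 0
            if s.name == "Western Australian":
                assert s.baseline_fracture_rate == pytest.approx(0.178)
            else:
                assert s.baseline_fracture_rate is None

    def test_correlation_dimension_matches_panel(self):
        for s in default_study_suite():
            assert s.correlation.k == len(s.site_panel)
            assert s.correlation.is_positive_definite()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            StudySpec("x", 0, (50, 60), ("FN",))
        with pytest.raises(ValueError):
            StudySpec("x", 10, (60, 50), ("FN",))
        with pytest.raises(ValueError):
            StudySpec("x", 10, (50, 60), ("FN", "BOGUS"))


class TestSimulateCohort:
    def test_null_configuration_has_no_carriers_and_centred_z(self, small_spec):
        records = simulate_cohort(
            small_spec, AlleleModel(carrier_frequency=0.0, effect=0.0), seed=3
        )
        assert sum(r.carrier for r in records) == 0
        zt = zscores(records, fit_all(records))
        for site, grp in zt.groupby("site"):
            assert abs(grp["z"].mean()) < 1e-10  # exact by OLS construction

    def test_carrier_prevalence_matches_heterozygote_probability(self):
        cf = 0.05
        spec = StudySpec("big", 20000, (50, 70), ("FN",))
        allele = AlleleModel(carrier_frequency=cf)
        # 2q - q^2 with q the implied allele frequency equals cf exactly
        q = allele.allele_frequency
        assert 2 * q - q**2 == pytest.approx(cf, abs=1e-12)
        records = simulate_cohort(spec, allele, seed=11)
        k = sum(r.carrier for r in records)
        se = math.sqrt(20000 * cf * (1 - cf))
        assert abs(k - 20000 * cf) <= 3 * se

    def test_mz_cotwins_share_carrier_status_and_allele(self):
        spec = StudySpec(
            "twins", 400, (20, 60), ("FN", "LS"),
            twin_fraction=0.6, dz_twin_fraction=0.2,
        )
        records = simulate_cohort(spec, AlleleModel(carrier_frequency=0.2), seed=5)
        pairs = {}
        for r in records:
            if r.zygosity == "MZ":
                pairs.setdefault(r.twin_pair_id, []).append(r)
        assert pairs, "expected MZ pairs"
        for pid, members in pairs.items():
            assert len(members) == 2
            assert members[0].carrier == members[1].carrier
            assert members[0].allele_label == members[1].allele_label
            assert members[0].age == members[1].age

    def test_latent_effect_recovered_in_adjusted_z(self):
        spec = StudySpec("eff", 5000, (50, 70), ("FN", "LS"))
        allele = AlleleModel(carrier_frequency=0.1, effect=-0.7)
        records = simulate_cohort(spec, allele, seed=13)
        zt = zscores(records, fit_all(records))
        carrier_mean = zt[zt["carrier"] == 1]["z"].mean()
        n_obs = (zt["carrier"] == 1).sum()
        assert abs(carrier_mean - (-0.7)) <= 3 / math.sqrt(n_obs)

    def test_generated_correlation_structure_recovered(self):
        """With no carrier effect, adjusted Z-scores reproduce the
        spec's inter-site correlation matrix."""
        from qrepbmd.monte_carlo import estimate_correlation

        spec = StudySpec("corr", 20_000, (50, 70), ("FN", "LS", "HIP", "BUA"))
        records = simulate_cohort(
            spec, AlleleModel(carrier_frequency=0.0, effect=0.0), seed=29
        )
        df = records_to_frame(records)
        zt = zscores(df, fit_all(df))
        est = estimate_correlation(zt, "corr")
        assert set(est.sites) == set(spec.site_panel)
        perm = [spec.site_panel.index(s) for s in est.sites]
        expected = spec.correlation.R[np.ix_(perm, perm)]
        assert np.abs(est.R - expected).max() < 0.05

    def test_fracture_odds_double_per_sd_deficit(self):
        p1 = fracture_probability(-1.0, 0.178)
        p0 = fracture_probability(0.0, 0.178)
        odds = lambda p: p / (1 - p)
        assert odds(p1) / odds(p0) == pytest.approx(2.0, rel=1e-12)

    def test_fracture_requires_fn_in_panel(self):
        spec = StudySpec(
            "nofn", 50, (50, 70), ("LS",), baseline_fracture_rate=0.178
        )
        with pytest.raises(ValueError, match="FN"):
            simulate_cohort(spec, AlleleModel(), seed=1)

    def test_carrier_counts_bracket_detection_interval(self):
        """Binomial sampling of carriers: ~12 expected per 3000 subjects at
        frequency 0.004, with 95% of replicates inside (6, 19)."""
        spec = StudySpec("det", 3000, (50, 70), ("FN",))
        allele = AlleleModel(carrier_frequency=0.004)
        rng_seeds = range(400)
        counts = np.array([
            sum(r.carrier for r in simulate_cohort(spec, allele, seed=s))
            for s in rng_seeds
        ])
        assert abs(counts.mean() - 12.0) < 1.0
        inside = ((counts >= 6) & (counts <= 19)).mean()
        # binomial SE of a 95% proportion over 400 replicates ~ 0.011
        assert inside >= 0.95 - 3 * 0.011


class TestAmpliconGeometry:
    def test_common_variants_shift_by_21_bp(self):
        wt = len(simulate_amplicon(23, 17, seed=1))
        assert len(simulate_amplicon(30, 17, seed=2)) - wt == 21
        assert len(simulate_amplicon(16, 17, seed=3)) - wt == -21

    @given(
        nq=st.integers(min_value=5, max_value=40),
        na=st.integers(min_value=0, max_value=30),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_length_affine_in_codon_count_with_slope_3(self, nq, na, seed):
        base = len(simulate_amplicon(23, 17, seed=0)) - 3 * (23 + 17)
        assert len(simulate_amplicon(nq, na, seed)) == base + 3 * (nq + na)

    def test_rejects_empty_glutamine_run(self):
        with pytest.raises(ValueError):
            simulate_amplicon(0, 17, seed=1)


class TestPhenotypeIO:
    def _roundtrip(self, records, tmp_path, name="p.csv"):
        path = tmp_path / name
        write_phenotypes(records, path)
        return read_phenotypes(path)

    def test_lossless_roundtrip(self, small_spec, enriched_allele, tmp_path):
        records = simulate_cohort(small_spec, enriched_allele, seed=21)
        back = self._roundtrip(records, tmp_path)
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert a.subject_id == b.subject_id
            assert a.carrier == b.carrier
            assert a.zygosity == b.zygosity
            assert a.allele_label == b.allele_label
            assert set(a.measures) == set(b.measures)
            for s in a.measures:
                assert a.measures[s] == pytest.approx(b.measures[s], rel=1e-12)

    def test_missing_field_stays_missing_not_zero(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(
            "subject_id,cohort,age,weight,height,twin_pair_id,zygosity,"
            "carrier,allele_label,prevalent_fracture,incident_fracture,FN,LS\n"
            "s1,c,60,65,160,,none,0,,0,0,0.85,\n"
        )
        (rec,) = read_phenotypes(path)
        assert "LS" not in rec.measures
        assert rec.measures["FN"] == pytest.approx(0.85)

    def test_zero_row_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text(
            "subject_id,cohort,age,weight,height,twin_pair_id,zygosity,"
            "carrier,allele_label,prevalent_fracture,incident_fracture,FN\n"
        )
        assert read_phenotypes(path) == []

    def test_unknown_site_column_named_in_error(self, tmp_path):
        path = tmp_path / "u.csv"
        path.write_text(
            "subject_id,cohort,age,weight,height,twin_pair_id,zygosity,"
            "carrier,allele_label,prevalent_fracture,incident_fracture,XYZ\n"
            "s1,c,60,65,160,,none,0,,0,0,1.0\n"
        )
        with pytest.raises(ValueError, match="XYZ"):
            read_phenotypes(path)

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "b.csv"
        path.write_text(
            "subject_id,cohort,age,weight,height,twin_pair_id,zygosity,"
            "carrier,allele_label,prevalent_fracture,incident_fracture,FN\n"
            "s1,c,60,65,160,,none,0,,0,0,0.8\n"
            "s2,c,sixty,65,160,,none,0,,0,0,0.8\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            read_phenotypes(path)
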