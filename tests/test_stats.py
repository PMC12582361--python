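import subprocess
import textwrap

import numpy as np
import pytest

from ecog_biomarkers.stats import (
    bonferroni_adjust,
    cohens_d_by_stage,
    fit_epi_glmm,
    fit_stage_lmm,
    log_variant,
    subtraction_predictor,
)
from ecog_biomarkers.synthetic_data import simulate_stats_table

from conftest import stats_table


def linear_table(slope=0.01, n_patients=4, n_channels=5, noise=0.0, seed=0):
    table = simulate_stats_table(
        n_patients=n_patients, n_channels=n_channels, slope=slope,
        sd_patient=0.05, sd_noise=noise, intercept=0.2, seed=seed,
    )
    return table


class TestStageLmm:
    def test_noise_free_recovery_exact(self):
        """On exactly linear data the stage estimate is the injected slope."""
        res = fit_stage_lmm(linear_table(), "MI")
        assert res.stage_estimate == pytest.approx(0.01, abs=1e-5)

    def test_noisy_recovery_and_significance(self):
        res = fit_stage_lmm(linear_table(noise=0.02, n_patients=8, n_channels=10, seed=3), "MI")
        assert res.converged
        assert res.stage_estimate == pytest.approx(0.01, abs=0.002)
        assert res.term("stage_code")["p_corrected"] < 0.05

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError, match="2 patients"):
            fit_stage_lmm(linear_table(n_patients=1), "MI")

    def test_residual_quantiles_exported(self):
        res = fit_stage_lmm(linear_table(noise=0.02, seed=1), "MI")
        assert res.residual_quantiles is not None
        assert len(res.residual_quantiles) == 101
        assert np.all(np.diff(res.residual_quantiles) >= 0)

    def test_bonferroni_m_six(self):
        res = fit_stage_lmm(linear_table(noise=0.02, seed=2), "MI")
        term = res.term("stage_code")
        assert term["p_corrected"] == pytest.approx(min(1.0, term["p"] * 6))

    def test_matches_lme4(self, tmp_path):
        """Independent cross-check: the stage slope agrees with lme4's REML fit."""
        table = linear_table(noise=0.02, n_patients=8, n_channels=6, seed=11)
        res = fit_stage_lmm(table, "MI")
        from ecog_biomarkers.stats import add_stage_codes

        df = add_stage_codes(table, "Iso")
        csv = tmp_path / "table.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(value ~ stage_code + age_years + sex + hemisphere + daily_seizures
                      + n_asm + factor(surgery_stages) + (1|patient_id), data=d, REML=TRUE)
            cat(sprintf("%.10f", fixef(m)[["stage_code"]]))
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        assert res.stage_estimate == pytest.approx(float(out.stdout.strip()), abs=1e-5)


class TestEpiGlmm:
    def _labelled_table(self, effect, n_patients=8, n_channels=40, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for p in range(n_patients):
            kw = dict(patient_id=f"P{p:02d}", hemisphere="LR"[p % 2], age_years=6.0 + p,
                      sex="MF"[p % 2], n_asm=p % 3, daily_seizures=bool(p % 2),
                      surgery_stages=1 + p % 2)
            for c in range(n_channels):
                v = rng.gamma(2.0, 0.5)
                eta = -0.5 + effect * v
                y = rng.random() < 1 / (1 + np.exp(-eta))
                rows.append((dict(is_resected=bool(y), **kw), f"C{c:02d}", "Sev3", 1, "MI", v))
        return stats_table(rows)

    def test_null_biomarker_or_near_one(self):
        res = fit_epi_glmm(self._labelled_table(effect=0.0, seed=4), "MI", "Sev3")
        term = res.term("value")
        assert abs(term["estimate"]) < 0.5
        assert term["p_corrected"] > 0.5

    def test_positive_effect_recovered(self):
        res = fit_epi_glmm(self._labelled_table(effect=2.0, seed=5), "MI", "Sev3",
                           standardize_value=False)
        assert 1.0 < res.term("value")["estimate"] < 3.0
        assert res.term("value")["odds_ratio"] > np.e

    def test_or_is_exp_estimate(self):
        res = fit_epi_glmm(self._labelled_table(effect=1.0, seed=6), "MI", "Sev3")
        term = res.term("value")
        assert term["odds_ratio"] == pytest.approx(np.exp(term["estimate"]))

    def test_single_class_rejected(self):
        table = self._labelled_table(effect=0.0, seed=7)
        table["is_resected"] = False
        with pytest.raises(ValueError, match="classes"):
            fit_epi_glmm(table, "MI", "Sev3")

    def test_soz_label_uses_soz_flag(self):
        table = self._labelled_table(effect=2.0, seed=8)
        table["is_soz"] = table["is_resected"]
        res = fit_epi_glmm(table, "MI", "Sev3", label="soz")
        assert res.term("value")["estimate"] > 0


class TestCohensD:
    def test_hand_computed_example(self):
        kw = dict(patient_id="P01")
        rows = [
            (dict(is_resected=True, **kw), "A", "Sev3", 1, "MI", 2.0),
            (dict(is_resected=True, **kw), "B", "Sev3", 1, "MI", 2.0),
            (dict(is_resected=False, **kw), "C", "Sev3", 1, "MI", 1.0),
            (dict(is_resected=False, **kw), "D", "Sev3", 1, "MI", 1.0),
            (dict(is_resected=False, **kw), "E", "Sev3", 1, "MI", 1.0),
        ]
        d = cohens_d_by_stage(stats_table(rows), "MI")
        expected = 1.0 / np.std([2, 2, 1, 1, 1], ddof=1)
        assert d["Sev3"] == pytest.approx(expected, abs=1e-12)
        assert d["Sev3"] == pytest.approx(1.826, abs=0.001)

    def test_equal_means_zero(self):
        kw = dict(patient_id="P01")
        rows = [
            (dict(is_resected=True, **kw), "A", "Sev3", 1, "MI", 1.0),
            (dict(is_resected=False, **kw), "B", "Sev3", 1, "MI", 1.0),
            (dict(is_resected=False, **kw), "C", "Sev3", 1, "MI", 2.0),
            (dict(is_resected=True, **kw), "D", "Sev3", 1, "MI", 2.0),
        ]
        assert cohens_d_by_stage(stats_table(rows), "MI")["Sev3"] == pytest.approx(0.0)

    def test_scale_invariance(self, rng):
        rows = []
        for ch in range(12):
            rows.append(
                (dict(patient_id="P01", is_resected=ch < 4), f"C{ch}", "Sev4", 1, "MI",
                 float(rng.gamma(2, 1)) + (0.5 if ch < 4 else 0.0))
            )
        t1 = stats_table(rows)
        t2 = t1.copy()
        t2["value"] *= 10
        d1 = cohens_d_by_stage(t1, "MI")["Sev4"]
        d2 = cohens_d_by_stage(t2, "MI")["Sev4"]
        assert d2 == pytest.approx(d1, rel=1e-12)

    def test_matches_brute_force_on_random_tables(self, rng):
        for seed in range(3):
            r = np.random.default_rng(seed)
            rows = []
            for p in range(3):
                for ep in (1, 2):
                    for ch in range(6):
                        rows.append((dict(patient_id=f"P{p}", is_resected=ch % 2 == 0),
                                     f"C{ch}", "Sev2", ep, "MI", float(r.gamma(2, 1))))
            table = stats_table(rows)
            # brute force
            ds = []
            for (pid, ep), g in table.groupby(["patient_id", "epoch_index"]):
                epi = g[g.is_resected]["value"]
                non = g[~g.is_resected.astype(bool)]["value"]
                ds.append(abs(epi.mean() - non.mean()) / g["value"].std(ddof=1))
            assert cohens_d_by_stage(table, "MI")["Sev2"] == pytest.approx(np.mean(ds))


class TestSubtraction:
    def test_arithmetic(self):
        kw = dict(patient_id="P01")
        rows = [
            (dict(is_resected=True, **kw), "A", "Sev4", 1, "MI", 3.0),
            (dict(is_resected=True, **kw), "B", "Sev4", 1, "MI", 1.0),
            (dict(is_resected=False, **kw), "C", "Sev4", 1, "MI", 1.0),
            (dict(is_resected=False, **kw), "D", "Sev4", 1, "MI", 1.0),
        ]
        s = subtraction_predictor(stats_table(rows), "MI", "Sev4")
        assert s["P01"] == pytest.approx(1.0)

    def test_identical_distributions_near_zero(self, rng):
        rows = []
        for ch in range(40):
            rows.append((dict(patient_id="P01", is_resected=ch < 20), f"C{ch}",
                         "Sev4", 1, "MI", float(rng.normal(1.0, 0.01))))
        s = subtraction_predictor(stats_table(rows), "MI", "Sev4")
        assert abs(s["P01"]) < 0.02

    def test_patient_missing_class_excluded(self):
        rows = [
            (dict(patient_id="P01", is_resected=True), "A", "Sev4", 1, "MI", 1.0),
            (dict(patient_id="P01", is_resected=False), "B", "Sev4", 1, "MI", 0.5),
            (dict(patient_id="P02", is_resected=False), "A", "Sev4", 1, "MI", 1.0),
        ]
        with pytest.warns(UserWarning, match="P02"):
            s = subtraction_predictor(stats_table(rows), "MI", "Sev4")
        assert list(s.index) == ["P01"]


@pytest.mark.parametrize(
    "p,m,expected", [(0.001, 40, 0.04), (0.5, 6, 1.0), (0.0, 99, 0.0), (0.02, 1, 0.02)]
)
def test_bonferroni(p, m, expected):
    assert bonferroni_adjust(p, m) == pytest.approx(expected)


def test_bonferroni_rejects_bad_input():
    with pytest.raises(ValueError):
        bonferroni_adjust(1.5, 6)
    with pytest.raises(ValueError):
        bonferroni_adjust(0.5, 0)


class TestLogVariant:
    def test_rank_preserving(self):
        table = linear_table(noise=0.01, seed=9)
        out = log_variant(table)
        assert (
            out["value"].rank().values == table["value"].rank().values
        ).all()

    def test_epsilon_only_when_zeros(self):
        table = linear_table(noise=0.0, seed=0)
        out = log_variant(table)
        np.testing.assert_allclose(out["value"], np.log(table["value"]))
        table2 = table.copy()
        table2.loc[table2.index[0], "value"] = 0.0
        out2 = log_variant(table2)
        eps = table2.loc[table2["value"] > 0, "value"].min() / 2
        assert out2["value"].iloc[0] == pytest.approx(np.log(eps))

    def test_all_zero_rejected(self):
        table = linear_table()
        table["value"] = 0.0
        with pytest.raises(ValueError, match="all values are zero"):
            log_variant(table)

    def test_stage_effect_sign_preserved(self):
        table = linear_table(slope=0.02, noise=0.01, n_patients=6, n_channels=8, seed=12)
        raw = fit_stage_lmm(table, "MI").stage_estimate
        logged = fit_stage_lmm(log_variant(table), "MI").stage_estimate
        assert raw > 0 and logged > 0
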