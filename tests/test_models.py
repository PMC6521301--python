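"""Covariate-adjusted variance-explained fits and stepwise selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grspipe import (
    GrsVector,
    SimulationConfig,
    fit_grs_model,
    refit_refined_grs,
    simulate_cohort,
    stepwise_select,
)
from grspipe.genotypes import GenotypeMatrix, SnpMeta
from grspipe.models import _design, _ols_pvalues, _prepare
from tests.conftest import truth_grs


def _pheno(n, delta, rng):
    return pd.DataFrame(
        {
            "participant_id": [f"p{i}" for i in range(n)],
            "age": rng.uniform(18, 40, n),
            "sex": rng.choice(["male", "female"], n),
            "bmi": rng.uniform(19, 29, n),
            "tg_pre": 100.0,
            "tg_post": 100.0 + delta,
        }
    )


def _vec(n, scores):
    return GrsVector("t", [], [f"p{i}" for i in range(n)],
                     np.asarray(scores))


class TestFitGrsModel:
    def test_noiseless_linear_outcome_gives_100_percent(self):
        rng = np.random.default_rng(0)
        n = 60
        scores = rng.integers(-5, 6, n)
        ph = _pheno(n, 3.0 * scores, rng)
        # covariates must not predict delta: freeze them to constants
        ph["age"], ph["bmi"], ph["sex"] = 25.0, 22.0, "female"
        fit = fit_grs_model(ph, _vec(n, scores))
        assert fit.grs_percent_variance == pytest.approx(100.0, abs=1e-8)
        assert fit.r2_full == pytest.approx(1.0)

    def test_constant_grs_flagged_inestimable(self):
        rng = np.random.default_rng(1)
        ph = _pheno(30, rng.normal(0, 10, 30), rng)
        fit = fit_grs_model(ph, _vec(30, np.zeros(30)))
        assert fit.grs_inestimable
        assert fit.grs_percent_variance == 0.0

    def test_nested_r2_ordering_and_nonnegative_increment(self, default_cohort,
                                                          classified):
        fit = fit_grs_model(classified.table, truth_grs(default_cohort))
        assert fit.r2_full >= fit.r2_covariates_only
        assert fit.grs_percent_variance >= 0
        assert 0 <= fit.partial_eta2_percent <= 100

    def test_incremental_r2_equals_squared_semipartial_correlation(
        self, default_cohort, classified
    ):
        """Closed-form check: increment = corr(delta, resid(GRS|covs))^2."""
        grs = truth_grs(default_cohort)
        fit = fit_grs_model(classified.table, grs)
        df = _prepare(classified.table).merge(grs.to_frame(), on="participant_id")
        x_cov = _design(df, ["age", "sex_male", "bmi"])
        g = df["score"].to_numpy(dtype=float)
        g_resid = g - x_cov @ np.linalg.lstsq(x_cov, g, rcond=None)[0]
        y = df["delta_tg"].to_numpy(dtype=float)
        semi = np.corrcoef(y, g_resid)[0, 1] ** 2
        assert fit.grs_percent_variance == pytest.approx(100 * semi, abs=1e-8)

    def test_invariant_to_affine_covariate_rescaling(self, default_cohort,
                                                     classified):
        grs = truth_grs(default_cohort)
        base = fit_grs_model(classified.table, grs)
        scaled = classified.table.copy()
        scaled["age"] = scaled["age"] * 12 + 7
        scaled["bmi"] = scaled["bmi"] / 3 - 2
        other = fit_grs_model(scaled, grs)
        assert other.grs_percent_variance == pytest.approx(
            base.grs_percent_variance, abs=1e-9
        )
        assert other.grs_p == pytest.approx(base.grs_p, abs=1e-12)

    def test_sex_reference_level_does_not_change_grs_statistics(
        self, default_cohort, classified
    ):
        grs = truth_grs(default_cohort)
        base = fit_grs_model(classified.table, grs)
        flipped = classified.table.copy()
        flipped["sex_male"] = 1.0 - (
            flipped["sex"].str.lower().eq("male").astype(float)
        )
        other = fit_grs_model(flipped, grs)
        assert other.grs_p == pytest.approx(base.grs_p, abs=1e-12)
        assert other.grs_percent_variance == pytest.approx(
            base.grs_percent_variance, abs=1e-9
        )

    def test_permutation_null_rejects_at_nominal_rate(self, default_cohort,
                                                      classified):
        """GRS permuted against delta TG: p-values uniform, ~5% below 0.05."""
        grs = truth_grs(default_cohort)
        rng = np.random.default_rng(99)
        scores = grs.scores.copy()
        rejections = 0
        n_perm = 500
        for _ in range(n_perm):
            perm = GrsVector("perm", [], grs.participant_ids,
                             rng.permutation(scores))
            rejections += fit_grs_model(classified.table, perm).grs_p < 0.05
        lo, hi = stats.binom.interval(0.999, n_perm, 0.05)
        assert lo <= rejections <= hi


def naive_stepwise(y, snp_cols, covs, entry_p, stay_p):
    """Independent oracle: exhaustively refit every candidate model per step
    with statsmodels, tracking the same entry/removal rule."""
    import statsmodels.api as sm

    included: list[str] = []
    log = []
    while True:
        changed = False
        pool = sorted(c for c in snp_cols if c not in included)
        entries = []
        for c in pool:
            x = np.column_stack(
                [np.ones(len(y))] + [snp_cols[k] for k in included]
                + [snp_cols[c]] + covs
            )
            p = sm.OLS(y, x).fit().pvalues[1 + len(included)]
            entries.append((p, c))
        if entries:
            p, c = min(entries)
            if p < entry_p:
                included.append(c)
                log.append((c, "enter", p))
                changed = True
        while included:
            x = np.column_stack(
                [np.ones(len(y))] + [snp_cols[k] for k in included] + covs
            )
            pv = sm.OLS(y, x).fit().pvalues[1 : 1 + len(included)]
            worst = int(np.argmax(pv))
            if pv[worst] > stay_p:
                c = included.pop(worst)
                log.append((c, "remove", float(pv[worst])))
                changed = True
            else:
                break
        if not changed:
            break
    return included, log


class TestStepwise:
    @pytest.fixture()
    def small_fixture(self):
        rng = np.random.default_rng(17)
        n = 60
        dosage = rng.integers(0, 3, (n, 4)).astype(float)
        delta = 6.0 * dosage[:, 1] - 5.0 * dosage[:, 3] + rng.normal(0, 8, n)
        ph = _pheno(n, delta, rng)
        mat = GenotypeMatrix(
            [f"p{i}" for i in range(n)],
            [SnpMeta(f"rs{j}") for j in range(4)], dosage,
        )
        return ph, mat

    def test_matches_exhaustive_refit_oracle(self, small_fixture):
        ph, mat = small_fixture
        res = stepwise_select(ph, mat, entry_p=0.15, stay_p=0.15)
        df = _prepare(ph)
        y = df["delta_tg"].to_numpy(dtype=float)
        snp_cols = {f"rs{j}": mat.dosage[:, j] for j in range(4)}
        covs = [df[c].to_numpy(dtype=float) for c in ("age", "sex_male", "bmi")]
        selected, log = naive_stepwise(y, snp_cols, covs, 0.15, 0.15)
        assert res.selected == selected
        assert [(r, a) for r, a, _ in res.log] == [(r, a) for r, a, _ in log]
        for (_, _, p1), (_, _, p2) in zip(res.log, log):
            assert p1 == pytest.approx(p2, abs=1e-10)

    def test_liberal_thresholds_select_all(self, small_fixture):
        ph, mat = small_fixture
        res = stepwise_select(ph, mat, entry_p=0.999999, stay_p=0.999999)
        assert sorted(res.selected) == [f"rs{j}" for j in range(4)]

    def test_strict_entry_selects_none(self, small_fixture):
        ph, mat = small_fixture
        res = stepwise_select(ph, mat, entry_p=1e-300, stay_p=1e-300)
        assert res.selected == []

    def test_invalid_thresholds_rejected(self, small_fixture):
        ph, mat = small_fixture
        with pytest.raises(ValueError):
            stepwise_select(ph, mat, entry_p=0.0)
        with pytest.raises(ValueError):
            stepwise_select(ph, mat, entry_p=0.1, stay_p=1.5)

    def test_planted_snp_selected_with_high_power(self):
        """One SNP explaining ~20% of variance among nulls, n=500."""
        hits = 0
        n_reps = 25
        for seed in range(n_reps):
            cfg = SimulationConfig(
                n_participants=500, n_snps=21, seed=2000 + seed,
                causal_snps=[(0, 15.0)], target_grs_partial_r2=0.2,
                covariate_effects=(0.0, 0.0, 0.0), baseline_coupling=0.0,
            )
            c = simulate_cohort(cfg)
            res = stepwise_select(c.phenotypes, c.genotypes)
            hits += c.genotypes.rsids[0] in res.selected
        assert hits >= int(0.95 * n_reps)

    def test_selected_terms_survive_stay_threshold(self, default_cohort,
                                                   classified):
        res = stepwise_select(classified.table, default_cohort.genotypes)
        df = _prepare(classified.table)
        geno = pd.DataFrame(
            {r: default_cohort.genotypes.column(r) for r in res.selected}
        ).assign(participant_id=default_cohort.genotypes.participant_ids)
        df = df.merge(geno, on="participant_id")
        y = df["delta_tg"].to_numpy(dtype=float)
        x = _design(df, res.selected + ["age", "sex_male", "bmi"])
        pvals = _ols_pvalues(y, x)[1 : 1 + len(res.selected)]
        assert (pvals <= res.stay_p).all()


class TestRefit:
    def test_full_panel_selection_is_delegation_identity(self, default_cohort,
                                                         classified,
                                                         responder_flags):
        from grspipe import compute_grs, compute_weights

        mat = default_cohort.genotypes
        w = compute_weights(mat, responder_flags)
        direct = fit_grs_model(classified.table, compute_grs(mat, w, mat.rsids))
        via = refit_refined_grs(mat, classified.table, mat.rsids, w)
        assert via.grs_percent_variance == pytest.approx(
            direct.grs_percent_variance
        )
        assert via.grs_p == pytest.approx(direct.grs_p)

    def test_empty_selection_rejected(self, default_cohort, classified):
        with pytest.raises(ValueError):
            refit_refined_grs(default_cohort.genotypes, classified.table, [], {})

    def test_refined_panel_beats_diluted_full_panel_on_average(self):
        """Scoring only the causal SNPs explains at least as much as adding
        98 noise SNPs, in most replicates (noise-SNP dilution)."""
        wins = 0
        n_reps = 20
        for seed in range(n_reps):
            c = simulate_cohort(SimulationConfig(seed=3000 + seed))
            ph = c.phenotypes
            truth_dirs = {t["rsid"]: t["risk_direction"]
                          for t in c.truth["causal_snps"]}
            from grspipe import compute_grs

            full_dirs = dict(truth_dirs)
            for r in c.genotypes.rsids:
                full_dirs.setdefault(r, 1)
            refined = fit_grs_model(
                ph, compute_grs(c.genotypes, truth_dirs, list(truth_dirs))
            ).grs_percent_variance
            full = fit_grs_model(
                ph, compute_grs(c.genotypes, full_dirs, c.genotypes.rsids)
            ).grs_percent_variance
            wins += refined >= full
        assert wins > n_reps / 2
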