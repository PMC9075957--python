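import numpy as np
import pandas as pd
import pytest
from scipy import stats

from poenet import ase
from poenet.simulate import AllelicCounts, GroundTruth, make_design, simulate_allelic_counts
from poenet.stats import fdr_ratio, score_critical_value


def _counts_from_matrices(L, S, design):
    return AllelicCounts(
        L=pd.DataFrame(L, columns=design["sample_id"]),
        S=pd.DataFrame(S, columns=design["sample_id"]),
        design=design,
    )


class TestUpperQuartileNormalize:
    def test_identical_samples_share_scale(self, f1_design):
        L = np.tile([[30], [60], [90]], (1, len(f1_design)))
        counts = _counts_from_matrices(L, L, f1_design)
        normalized, _ = ase.upper_quartile_normalize(counts, min_depth=0)
        assert np.allclose(normalized.to_numpy(), normalized.to_numpy()[:, [0]])

    def test_doubled_library_normalizes_away(self):
        design = make_design(1, "F1").iloc[:2].copy()
        L = np.array([[10, 20], [40, 80], [25, 50]])
        counts = _counts_from_matrices(L, L, design)
        normalized, _ = ase.upper_quartile_normalize(counts, min_depth=0)
        assert np.allclose(normalized.iloc[:, 0], normalized.iloc[:, 1])

    def test_min_depth_boundary_masks(self):
        design = make_design(1, "F1").iloc[:2].copy()
        # identical samples -> scale 1, so normalized depth = raw total
        L = np.array([[10, 10], [100, 100]])
        S = np.array([[9, 9], [100, 100]])  # gene 0 total 19.5 avg -> 19 < 20
        counts = _counts_from_matrices(L, S, design)
        _, retained = ase.upper_quartile_normalize(counts, min_depth=20)
        assert not retained.iloc[0] and retained.iloc[1]

    def test_all_zero_sample_rejected(self):
        design = make_design(1, "F1").iloc[:2].copy()
        Z = np.zeros((2, 2), dtype=int)
        counts = _counts_from_matrices(np.array([[1, 0], [2, 0]]), Z, design)
        with pytest.raises(ValueError, match="no nonzero totals"):
            ase.upper_quartile_normalize(counts)


class TestLbias:
    @pytest.mark.parametrize("l,s,expected", [(30, 10, 0.75), (98, 2, 0.98), (0, 5, 0.0)])
    def test_ratio(self, l, s, expected, f1_design):
        counts = _counts_from_matrices(
            np.full((1, len(f1_design)), l), np.full((1, len(f1_design)), s), f1_design
        )
        assert ase.compute_lbias(counts).iloc[0, 0] == pytest.approx(expected)

    def test_zero_total_is_missing(self, f1_design):
        counts = _counts_from_matrices(
            np.zeros((1, len(f1_design)), int), np.zeros((1, len(f1_design)), int), f1_design
        )
        assert ase.compute_lbias(counts).isna().all().all()


class TestBetaBinomialFit:
    def test_rho_identity_at_complexity_boundary(self):
        fit = ase.BetaBinomFit(alpha=9.5, beta=9.5)
        assert fit.rho == pytest.approx(1.0 / 20.0)
        assert not fit.complex_library  # rho = 0.05 is not < 0.05

    def test_recovers_planted_dispersion(self, rng):
        # alpha = beta = 2 -> rho = 0.2
        n, depth = 2000, 100
        p = rng.beta(2.0, 2.0, n)
        L = rng.binomial(depth, p)
        fit = ase.fit_beta_binomial(L, np.full(n, depth))
        assert 0.17 <= fit.rho <= 0.23

    def test_binomial_data_has_tiny_dispersion(self, rng):
        n, depth = 3000, 200
        L = rng.binomial(depth, 0.5, n)
        fit = ase.fit_beta_binomial(L, np.full(n, depth))
        assert fit.rho < 0.01
        assert fit.complex_library

    def test_degenerate_data_flags_boundary(self):
        T = np.full(20, 50)
        fit = ase.fit_beta_binomial(np.zeros(20), T)
        assert fit.boundary

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            ase.fit_beta_binomial(np.arange(5), np.full(5, 10))


class TestModelSelection:
    def test_full_design_selects_full_model(self, full_design):
        assert ase.select_ase_model(full_design) == "full"

    def test_sparse_sex_cell_falls_back_to_diet_model(self, f1_design):
        # remove all-but-one sample from the (LxS, F) cells while keeping
        # every cross:diet cell at >= 2
        design = f1_design.copy()
        drop = design[(design.cross == "LxS") & (design.sex == "F")].index[1:-1]
        design = design.drop(drop[: len(drop) - 1])
        sub = design[(design.cross == "LxS") & (design.sex == "F")]
        if len(sub) > 1:
            design = design.drop(sub.index[1:])
        counts = design.groupby(["cross", "diet"]).size()
        assume_ok = counts.min() >= 2
        assert assume_ok
        assert ase.select_ase_model(design) == "cross_diet"

    def test_single_cross_sample_untestable(self, f1_design):
        design = pd.concat(
            [
                f1_design[f1_design.cross == "SxL"],
                f1_design[f1_design.cross == "LxS"].iloc[:1],
            ]
        )
        assert ase.select_ase_model(design) == "untestable"

    def test_deterministic(self, full_design):
        assert ase.select_ase_model(full_design) == ase.select_ase_model(full_design)


class TestPoeTest:
    def test_strong_imprinting_is_overwhelming(self):
        design = make_design(3, "F1")  # 12 per cross
        lbias = np.where(design.cross == "SxL", 0.98, 0.02) + np.linspace(0, 1e-3, len(design))
        p, _ = ase.test_poe_ase(lbias, design, "cross")
        # oracle: one-way ANOVA over crosses
        groups = [lbias[(design.cross == c).to_numpy()] for c in ("LxS", "SxL")]
        p_oracle = stats.f_oneway(*groups).pvalue
        assert p == pytest.approx(p_oracle, rel=1e-10)
        assert p < 1e-10

    def test_identical_crosses_not_significant(self, f1_design):
        base = np.tile([0.4, 0.5, 0.6, 0.5], len(f1_design) // 4)
        p, _ = ase.test_poe_ase(base, f1_design, "cross")
        assert p > 0.5

    def test_null_pvalues_uniform(self, f1_design):
        rng = np.random.default_rng(31)
        n_genes = 1000
        lbias = pd.DataFrame(
            rng.beta(20, 20, size=(n_genes, len(f1_design))),
            columns=f1_design["sample_id"],
        )
        pvals, _ = ase._scan_pvalues(lbias, f1_design)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPermutationNullAse:
    def test_bookkeeping_and_determinism(self, allelic_counts, f1_design):
        lbias = ase.compute_lbias(allelic_counts)
        null1 = ase.permute_context_null(lbias, f1_design, n_iterations=3, seed=5)
        null2 = ase.permute_context_null(lbias, f1_design, n_iterations=3, seed=5)
        assert null1.pooled_size == 3 * len(lbias)
        assert np.array_equal(null1.values, null2.values)

    def test_null_uniform_under_biallelic_data(self, f1_design):
        rng = np.random.default_rng(17)
        lbias = pd.DataFrame(
            rng.beta(30, 30, size=(400, len(f1_design))), columns=f1_design["sample_id"]
        )
        null = ase.permute_context_null(lbias, f1_design, n_iterations=3, seed=1)
        assert stats.kstest(null.values, "uniform").pvalue > 0.01


class TestFdrRatio:
    def test_worked_ratio(self):
        real = np.concatenate([np.full(2, 0.005), np.full(8, 0.5)])
        null = np.concatenate([np.full(5, 0.005), np.full(45, 0.5)])
        assert fdr_ratio(real, null, 0.01) == pytest.approx((5 / 50) / (2 / 10))

    def test_identical_distributions_give_unity(self, rng):
        p = rng.uniform(0, 1, 2000)
        for t in (0.05, 0.2, 0.5):
            assert fdr_ratio(p, p, t) == pytest.approx(1.0)

    def test_separated_distributions_give_zero(self):
        real = np.full(100, 1e-6)
        null = np.full(1000, 0.5)
        assert fdr_ratio(real, null, 1e-5) == 0.0

    def test_no_real_hits_is_flagged_undefined(self):
        assert np.isnan(fdr_ratio(np.full(10, 0.9), np.full(10, 0.5), 0.01))

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            fdr_ratio(np.array([0.1]), np.array([]), 0.05)


class TestPoeScore:
    @pytest.mark.parametrize(
        "sxl_bias,lxs_bias,expected", [(1.0, 0.0, 1.0), (0.5, 0.5, 0.0), (0.0, 1.0, -1.0)]
    )
    def test_endpoints(self, f1_design, sxl_bias, lxs_bias, expected):
        lbias = pd.DataFrame(
            [np.where(f1_design.cross == "SxL", sxl_bias, lxs_bias)],
            columns=f1_design["sample_id"],
        )
        assert ase.poe_score(lbias, f1_design).iloc[0] == pytest.approx(expected)

    def test_missing_cross_gives_missing_score(self, f1_design):
        design = f1_design[f1_design.cross == "SxL"]
        lbias = pd.DataFrame([np.ones(len(design))], columns=design["sample_id"])
        assert ase.poe_score(lbias, design).isna().all()

    def test_per_context_scores_expose_bipolar_genes(self, f1_design):
        # paternal in HF, maternal in LF: pooled score cancels
        hf = (f1_design.diet == "HF").to_numpy()
        sxl = (f1_design.cross == "SxL").to_numpy()
        vals = np.where(hf, np.where(sxl, 1.0, 0.0), np.where(sxl, 0.0, 1.0))
        lbias = pd.DataFrame([vals], columns=f1_design["sample_id"])
        pooled = ase.poe_score(lbias, f1_design).iloc[0]
        ctx = ase.poe_score(lbias, f1_design, by_context=True)
        assert abs(pooled) < 1e-12
        assert ctx.loc[0, "F_HF"] == pytest.approx(1.0)
        assert ctx.loc[0, "F_LF"] == pytest.approx(-1.0)


class TestScoreCriticalValue:
    def test_uniform_null_quantiles(self, rng):
        null = rng.uniform(-0.1, 0.1, 200_000)
        lo, hi = score_critical_value(null, alpha=0.01)
        assert lo == pytest.approx(-0.099, abs=2e-3)
        assert hi == pytest.approx(0.099, abs=2e-3)

    def test_symmetric_null_symmetric_thresholds(self, rng):
        null = rng.normal(0, 0.05, 100_000)
        lo, hi = score_critical_value(null, alpha=0.05)
        assert lo == pytest.approx(-hi, abs=2e-3)

    def test_alpha_one_collapses_to_median(self):
        null = np.arange(101) / 100
        lo, hi = score_critical_value(null, alpha=1.0)
        assert lo == hi == pytest.approx(np.median(null))


class TestPlantedRecovery:
    def test_sensitivity_and_fdp(self):
        design = make_design(4, "F1")
        genes = [f"g{i:04d}" for i in range(400)]
        rng = np.random.default_rng(99)
        planted = {}
        for g in genes[:20]:
            pat = rng.random() < 0.5
            planted[g] = {"LxS": 0.02 if pat else 0.98, "SxL": 0.98 if pat else 0.02}
        truth = GroundTruth(ase_genes=planted)
        sens, fdps = [], []
        for seed in range(3):
            counts = simulate_allelic_counts(design, truth, genes, depth_mean=100, seed=seed)
            result = ase.ase_scan(counts, n_iterations=5, seed=seed + 100)
            sig = set(result.index[result.significant])
            tp = len(sig & set(planted))
            sens.append(tp / len(planted))
            fdps.append((len(sig) - tp) / max(len(sig), 1))
        assert np.mean(sens) >= 0.9
        assert np.mean(fdps) <= 0.2
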