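import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from poenet import scrna
from poenet.simulate import make_cluster_profiles, simulate_cells


class TestQcFilter:
    def _cells(self, n_features, n_counts):
        """Build cells whose QC metrics equal the given targets exactly."""
        n_genes = int(max(n_features)) + 10
        rows = []
        for nf, nc in zip(n_features, n_counts):
            row = np.zeros(n_genes)
            nf = int(nf)
            base = (int(nc) - nf) // nf
            row[:nf] = base + 1
            row[0] += int(nc) - (base + 1) * nf
            rows.append(row)
        return pd.DataFrame(rows, index=[f"c{i}" for i in range(len(rows))])

    def test_range_bounds_inclusive(self):
        nf = [400, 500, 1500, 3000, 3100] + [1500] * 10
        nc = [2000, 1000, 5000, 30000, 20000] + [5000] * 10
        cells = self._cells(nf, nc)
        kept, qc = scrna.qc_filter(cells, resid_sd=50)  # disable residual rule
        assert "c0" not in kept  # 400 features: below lower bound
        assert "c1" in kept      # exactly 500 features / 1000 counts: kept
        assert "c3" in kept      # exactly 3000 / 30000: kept
        assert "c4" not in kept  # 3100 features: above upper bound

    def test_on_curve_cells_pass_residual_rule(self):
        rng = np.random.default_rng(0)
        nc = rng.integers(2000, 20000, 60)
        nf = (0.1 * nc + 500).astype(int)  # exact smooth relation
        cells = self._cells(nf, nc)
        kept, _ = scrna.qc_filter(cells)
        assert len(kept) == 60

    def test_covariation_outlier_removed(self):
        rng = np.random.default_rng(1)
        nc = rng.integers(2000, 20000, 80)
        nf = (0.1 * nc + 500 + rng.normal(0, 10, 80)).astype(int)
        nf[0] = 2800  # far off the curve but inside the feature range
        cells = self._cells(nf, nc)
        kept, qc = scrna.qc_filter(cells)
        assert "c0" not in kept

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            scrna.qc_filter(pd.DataFrame(np.ones((5, 10))))


class TestNormalizeCells:
    def test_seurat_formula(self):
        cells = pd.DataFrame([[10, 9990]], columns=["g1", "g2"], index=["c"])
        norm = scrna.normalize_cells(cells)
        assert norm.loc["c", "g1"] == pytest.approx(np.log(11.0))

    def test_zero_count_stays_zero(self):
        cells = pd.DataFrame([[0, 100]], columns=["g1", "g2"])
        assert scrna.normalize_cells(cells).iloc[0, 0] == 0.0

    def test_depth_invariance(self, rng):
        cells = pd.DataFrame(rng.poisson(5, (4, 30)) + 1)
        doubled = cells * 2
        pd.testing.assert_frame_equal(
            scrna.normalize_cells(cells), scrna.normalize_cells(doubled)
        )


class TestClusterVariances:
    def test_constant_expressers_give_zero(self):
        expr = np.array([2.0, 2.0, 2.0, 3.0, 3.0, 3.0])
        labels = np.array(["a"] * 3 + ["b"] * 3)
        assert scrna.count_variance(expr, labels) == 0.0

    def test_mean_of_cluster_sds(self):
        # cluster a has SD 1, cluster b has SD 3 (over expressing cells)
        expr = np.array([4.0, 6.0, 4.0, 10.0])
        labels = np.array(["a", "a", "b", "b"])
        sd_a = np.std([4.0, 6.0], ddof=1)
        sd_b = np.std([4.0, 10.0], ddof=1)
        assert scrna.count_variance(expr, labels) == pytest.approx((sd_a + sd_b) / 2)

    def test_non_expressing_cells_ignored(self, rng):
        expr = rng.gamma(2, 1, 60) + 0.1
        labels = np.repeat(["a", "b", "c"], 20)
        base = scrna.count_variance(expr, labels)
        padded_expr = np.concatenate([expr, np.zeros(30)])
        padded_labels = np.concatenate([labels, np.repeat(["a", "b", "c"], 10)])
        assert scrna.count_variance(padded_expr, padded_labels) == pytest.approx(base)

    def test_pct_expressing_variance_worked_example(self):
        # two clusters at 20% and 80% expressing
        expr = np.array([1, 0, 0, 0, 0, 1, 1, 1, 1, 0], dtype=float)
        labels = np.repeat(["a", "b"], 5)
        assert scrna.pct_expressing_variance(expr, labels) == pytest.approx(
            np.std([0.2, 0.8], ddof=1)
        )

    def test_pct_variance_ignores_cluster_sizes(self):
        expr_small = np.array([1.0, 0.0, 1.0, 1.0])
        labels_small = np.array(["a", "a", "b", "b"])
        expr_big = np.array([1.0, 0.0] * 10 + [1.0, 1.0] * 10)
        labels_big = np.array(["a"] * 20 + ["b"] * 20)
        assert scrna.pct_expressing_variance(
            expr_small, labels_small
        ) == pytest.approx(scrna.pct_expressing_variance(expr_big, labels_big))

    def test_equal_percentages_give_zero(self):
        expr = np.array([1.0, 0.0, 1.0, 0.0])
        labels = np.array(["a", "a", "b", "b"])
        assert scrna.pct_expressing_variance(expr, labels) == 0.0


def _staircase_labelings(targets):
    """One marker vector + per-resolution labelings with prescribed count variances.

    A two-cell cluster with values {10, 10 + c * sqrt(2)} has sample SD c;
    at resolution i only pair i forms a cluster of two expressing cells
    (every other cell is a singleton and is skipped), so the count variance
    at resolution i equals targets[i] exactly.
    """
    marker = []
    for c in targets:
        marker += [10.0, 10.0 + c * np.sqrt(2.0)]
    marker = np.array(marker)
    labelings = {}
    for i in range(len(targets)):
        labels = np.array([f"solo{j}" for j in range(marker.size)], dtype=object)
        labels[2 * i] = labels[2 * i + 1] = "pair"
        labelings[i] = labels
    return marker, labelings


class TestSelectResolution:
    def test_plateau_rule_hand_trace(self):
        targets = [5.0, 3.0, 1.0, 1.01, 1.0]
        marker, labelings = _staircase_labelings(targets)
        resolutions = list(range(5))
        chosen, cvars = scrna.select_resolution(resolutions, labelings, marker, tol=0.05)
        assert np.allclose(cvars, targets, atol=1e-9)
        assert chosen == 2  # independently hand-traced: lowest on the plateau
        assert chosen == _apply_plateau_rule(resolutions, list(cvars), 0.05)

    def test_flat_sequence_picks_first(self):
        marker = np.array([4.0, 6.0, 4.0, 6.0])
        labels = {r: np.array(["a", "a", "b", "b"]) for r in ("r1", "r2", "r3")}
        chosen, cvars = scrna.select_resolution(["r1", "r2", "r3"], labels, marker)
        assert chosen == "r1"
        assert np.allclose(cvars, cvars[0])

    def test_no_plateau_warns_and_returns_last(self):
        # strictly decreasing count variance across resolutions
        exprs = {
            "r1": 8.0, "r2": 4.0, "r3": 1.0,
        }
        marker = np.array([5 - 8, 5 + 8, 5 - 4, 5 + 4, 5 - 1, 5 + 1], dtype=float) + 10
        labels = {
            "r1": np.array(["a", "a", "x", "y", "w", "z"]),
            "r2": np.array(["x", "y", "b", "b", "w", "z"]),
            "r3": np.array(["x", "y", "w", "z", "c", "c"]),
        }
        with pytest.warns(RuntimeWarning, match="no plateau"):
            chosen, cvars = scrna.select_resolution(["r1", "r2", "r3"], labels, marker)
        assert chosen == "r3"
        assert cvars[0] > cvars[1] > cvars[2]

    def test_too_few_resolutions_rejected(self):
        with pytest.raises(ValueError):
            scrna.select_resolution(["r1", "r2"], {}, np.array([1.0]))


def _apply_plateau_rule(resolutions, cvars, tol):
    """Independent hand-rule trace used as the oracle for select_resolution."""
    vmin = min(cvars)
    for i, c in enumerate(cvars):
        if c > vmin * (1 + tol):
            continue
        if i == len(cvars) - 1 or abs(cvars[i + 1] - c) <= tol * c:
            return i
    return len(cvars) - 1


class TestSelectResolutionAgainstOracle:
    def test_matches_hand_rule_on_synthetic_clusterings(self):
        rng = np.random.default_rng(3)
        profiles = make_cluster_profiles(n_clusters=3, n_genes=30, marker_max=8, seed=1)
        cells, labels = simulate_cells(300, profiles, seed=2)
        norm = scrna.normalize_cells(cells)
        marker = norm["marker"].to_numpy()
        resolutions = [0.1, 0.2, 0.3, 0.4]
        per_res = {r: scrna.kmeans_cluster(norm, r, seed=0) for r in resolutions}
        chosen, cvars = scrna.select_resolution(resolutions, per_res, marker)
        oracle = resolutions[_apply_plateau_rule(resolutions, list(cvars), 0.05)]
        assert chosen == oracle


class TestPctDelta:
    @pytest.mark.parametrize(
        "p1,p2,expected", [(0.2, 0.8, 0.75), (0.5, 0.5, 0.0), (0.0, 0.4, 1.0)]
    )
    def test_worked_values(self, p1, p2, expected):
        assert scrna.pct_delta(p1, p2) == pytest.approx(expected)

    def test_both_zero_missing(self):
        assert np.isnan(scrna.pct_delta(0.0, 0.0))

    @given(
        p1=st.floats(min_value=0, max_value=1),
        p2=st.floats(min_value=0, max_value=1),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_symmetric(self, p1, p2):
        if p1 == 0 and p2 == 0:
            return
        d = scrna.pct_delta(p1, p2)
        assert 0.0 <= d <= 1.0
        assert d == scrna.pct_delta(p2, p1)


class TestTrajectoryDe:
    def test_planted_marker_flagged(self):
        profiles = make_cluster_profiles(n_clusters=2, n_genes=100, marker_max=10, seed=4)
        cells, labels = simulate_cells(400, profiles, seed=5)
        norm = scrna.normalize_cells(cells)
        table = scrna.trajectory_de(
            norm[(labels == "cluster0").to_numpy()],
            norm[(labels == "cluster1").to_numpy()],
        ).set_index("gene")
        assert bool(table.loc["marker", "significant"])
        assert table.loc["marker", "pct_delta"] > 0.9

    def test_identical_clusters_mostly_clean(self):
        flagged = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            profiles = pd.DataFrame(
                np.tile(rng.gamma(2, 1, 200), (2, 1)),
                index=["a", "b"],
                columns=[f"g{i}" for i in range(200)],
            )
            cells, labels = simulate_cells(300, profiles, seed=seed + 10)
            norm = scrna.normalize_cells(cells + (cells.sum(axis=1) == 0).to_numpy()[:, None])
            table = scrna.trajectory_de(
                norm[(labels == "a").to_numpy()], norm[(labels == "b").to_numpy()]
            )
            flagged.append(int(table["significant"].sum()))
        assert np.mean([f == 0 for f in flagged]) >= 0.9

    def test_effect_filter_blocks_weak_changes(self):
        table = pd.DataFrame(
            {"p_adj": [1e-6], "log2fc": [0.2], "pct_delta": [0.3]}
        )
        significant = (table["p_adj"] <= 0.05) & (
            (table["log2fc"].abs() >= 0.3) | (table["pct_delta"] >= 0.4)
        )
        assert not significant.iloc[0]

    def test_small_clusters_rejected(self):
        df = pd.DataFrame(np.ones((2, 3)))
        with pytest.raises(ValueError):
            scrna.trajectory_de(df, df)
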