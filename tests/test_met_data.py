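import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from envgxe.met_data import (
    DEFAULT_MAX_WEIGHT, ECMatrix, FormatError, MetMeans, PlotRecords,
    read_ec_csv, read_plot_csv, stage1_adjust, stage1_adjust_trial,
    standardize_ec, write_ec_csv, write_plot_csv,
)


def _rcbd_frame(yields, genos=("A", "B", "C"), blocks=("1", "2")):
    rows = []
    k = 0
    for b in blocks:
        for g in genos:
            rows.append((g, "loc", "2001", b, yields[k]))
            k += 1
    return pd.DataFrame(rows, columns=["genotype", "location", "year",
                                       "block", "yield"])


class TestPlotIO:
    def test_roundtrip(self, tmp_path):
        df = _rcbd_frame([1.0, 2.0, 3.0, 1.5, 2.5, 3.5])
        plots = PlotRecords(df)
        path = tmp_path / "plots.csv"
        write_plot_csv(plots, path)
        back = read_plot_csv(path)
        assert np.allclose(back.data["yield"], plots.data["yield"], atol=1e-12)
        assert list(back.data["genotype"]) == list(plots.data["genotype"])

    def test_duplicate_key_named_in_error(self):
        df = _rcbd_frame([1, 2, 3, 4, 5, 6])
        df.loc[1, ["genotype", "block"]] = ["A", "1"]
        with pytest.raises(FormatError, match="duplicate.*A.*loc.*2001.*1"):
            PlotRecords(df)

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("genotype,location,year,block,yield\n")
        assert len(read_plot_csv(path)) == 0

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("genotype,location,year,block\nA,l,2001,1\n")
        with pytest.raises(FormatError, match="missing columns"):
            read_plot_csv(path)

    def test_non_numeric_yield(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("genotype,location,year,block,yield\nA,l,2001,1,oops\n")
        with pytest.raises(FormatError, match="non-finite or non-numeric"):
            read_plot_csv(path)

    def test_column_mapping(self, tmp_path):
        path = tmp_path / "mapped.csv"
        path.write_text("gen,site,yr,rep,t_ha\nA,l,2001,1,4.2\nB,l,2001,1,4.4\n")
        plots = read_plot_csv(path, column_map={
            "genotype": "gen", "location": "site", "year": "yr",
            "block": "rep", "yield": "t_ha"})
        assert plots.data["yield"].tolist() == [4.2, 4.4]


class TestStage1:
    def test_balanced_equals_raw_means_with_closed_form_weight(self):
        rng = np.random.default_rng(0)
        genos = [f"g{i}" for i in range(5)]
        blocks = ["1", "2", "3"]
        rows = []
        mu = {g: 3 + 0.2 * i for i, g in enumerate(genos)}
        for b in blocks:
            off = rng.normal(0, 0.3)
            for g in genos:
                rows.append((g, "l", "2001", b, mu[g] + off + rng.normal(0, 0.2)))
        plots = PlotRecords(pd.DataFrame(rows, columns=[
            "genotype", "location", "year", "block", "yield"]))
        out = stage1_adjust_trial(plots, "l", "2001")
        raw = plots.data.groupby("genotype")["mean" if False else "yield"].mean()
        assert np.allclose(out.set_index("genotype")["mean"], raw, atol=1e-10)
        # balanced LS-mean variance is sigma2/R
        df_resid = 15 - (1 + 2 + 4)
        X = np.ones((15, 7))
        # independent sigma2: two-way ANOVA residual
        piv = plots.data.pivot(index="genotype", columns="block", values="yield")
        resid = piv - piv.mean(1).values[:, None] - piv.mean(0).values + piv.values.mean()
        sigma2 = (resid.values ** 2).sum() / df_resid
        assert np.allclose(out["weight"], 3 / sigma2, rtol=1e-10)

    def test_balanced_weight_matches_simulated_estimator_variance(self):
        """Weight^-1 equals the true sampling variance sigma2/R of the LS mean.

        The adjusted mean is linear in the plot data; probing the map with
        basis vectors and simulating 1e4 noise draws gives its brute-force
        sampling variance.
        """
        rng = np.random.default_rng(1)
        genos, blocks = ["a", "b", "c", "d"], ["1", "2", "3"]
        base = _rcbd_frame(np.zeros(12), genos=genos, blocks=blocks)

        def estimator(y):
            base["yield"] = y
            out = stage1_adjust_trial(PlotRecords(base.copy()), "loc", "2001")
            return out.loc[out["genotype"] == "a", "mean"].iloc[0]

        K = np.array([estimator(row) for row in np.eye(12)])
        sigma, n_sim = 0.4, 10_000
        draws = rng.normal(0, sigma, (n_sim, 12)) @ K
        emp_var = draws.var(ddof=1)
        true_var = sigma ** 2 / 3
        assert abs(emp_var - true_var) < 4 * true_var * np.sqrt(2 / n_sim)

    def test_missing_plot_matches_normal_equations(self):
        rng = np.random.default_rng(2)
        df = _rcbd_frame(rng.normal(4, 0.5, 6))
        df = df.drop(index=5).reset_index(drop=True)  # genotype C missing in block 2
        plots = PlotRecords(df)
        out = stage1_adjust_trial(plots, "loc", "2001").set_index("genotype")
        # independent oracle: overparameterized normal equations with pinv,
        # LS mean = average prediction of the genotype over all blocks
        genos, blocks = ["A", "B", "C"], ["1", "2"]
        Z = np.zeros((len(df), 1 + 2 + 3))
        Z[:, 0] = 1
        for r, row in df.iterrows():
            Z[r, 1 + blocks.index(row["block"])] = 1
            Z[r, 3 + genos.index(row["genotype"])] = 1
        beta = np.linalg.pinv(Z) @ df["yield"].to_numpy()
        for gi, g in enumerate(genos):
            preds = [beta[0] + beta[1 + b] + beta[3 + gi] for b in range(2)]
            assert np.isclose(out.loc[g, "mean"], np.mean(preds), atol=1e-9)
        raw_c = df[df["genotype"] == "C"]["yield"].mean()
        assert not np.isclose(out.loc["C", "mean"], raw_c)

    def test_constant_yields_capped_weight(self, caplog):
        plots = PlotRecords(_rcbd_frame([2.0] * 6))
        out = stage1_adjust_trial(plots, "loc", "2001")
        assert np.allclose(out["mean"], 2.0)
        assert np.allclose(out["weight"], DEFAULT_MAX_WEIGHT)

    def test_degenerate_designs(self):
        one_block = _rcbd_frame([1, 2, 3, 4, 5, 6])
        one_block["block"] = "1"
        one_block = one_block.drop_duplicates(["genotype", "block"])
        with pytest.raises(ValueError, match="fewer than 2 blocks"):
            stage1_adjust_trial(PlotRecords(one_block), "loc", "2001")
        # 2 genotypes x 2 blocks minus one plot: zero residual df
        df = _rcbd_frame([1, 2, 3, 4], genos=("A", "B"))
        df = df.drop(index=3)
        with pytest.raises(ValueError, match="zero residual"):
            stage1_adjust_trial(PlotRecords(df), "loc", "2001")

    def test_stage1_adjust_all_trials(self):
        rng = np.random.default_rng(3)
        frames = []
        for loc in ("l1", "l2"):
            f = _rcbd_frame(rng.normal(4, 0.5, 6))
            f["location"] = loc
            frames.append(f)
        plots = PlotRecords(pd.concat(frames, ignore_index=True))
        means = stage1_adjust(plots)
        assert len(means) == 6
        assert set(means.environments()) == {("l1", "2001"), ("l2", "2001")}


class TestECMatrix:
    def test_standardize_arithmetic(self):
        ec = ECMatrix([("a", "1"), ("b", "1"), ("c", "1")],
                      np.array([[1.0], [2.0], [3.0]]), ["x"])
        out = standardize_ec(ec)
        assert np.allclose(out.values[:, 0], [-1, 0, 1])
        assert out.centers[0] == 2 and out.scales[0] == 1

    def test_standardize_idempotent_and_invertible(self):
        rng = np.random.default_rng(4)
        ec = ECMatrix([(f"l{i}", "1") for i in range(6)],
                      rng.normal(2, 3, (6, 3)), ["a", "b", "c"])
        s1 = standardize_ec(ec)
        s2 = standardize_ec(s1)
        assert np.allclose(s1.values, s2.values, atol=1e-12)
        # stored metadata maps raw rows to the standardized scale
        assert np.allclose(s2.apply_standardization(ec.values), s1.values,
                           atol=1e-12)

    def test_heldout_row_standardization(self):
        ec = ECMatrix([("a", "1"), ("b", "1")], np.array([[1.0], [3.0]]), ["x"])
        s = standardize_ec(ec)
        x = s.apply_standardization(np.array([5.0]))
        assert np.allclose(x, (5 - 2) / np.sqrt(2))

    def test_constant_column_error(self):
        ec = ECMatrix([("a", "1"), ("b", "1")], np.array([[1.0, 7.0], [2.0, 7.0]]),
                      ["x", "const"])
        with pytest.raises(ValueError, match="const"):
            standardize_ec(ec)

    def test_csv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        ec = ECMatrix([("l1", "2001"), ("l1", "2002"), ("l2", "2001")],
                      rng.normal(size=(3, 2)), ["rain", "temp"])
        path = tmp_path / "ec.csv"
        write_ec_csv(ec, path)
        back = read_ec_csv(path)
        assert np.allclose(back.values, ec.values, atol=1e-12)
        assert back.environments == ec.environments

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(2, 8), st.integers(1, 4), st.integers(0, 1000))
    def test_standardized_columns_property(self, n_env, p, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(5, 4, (n_env, p))
        vals[:, 0] += np.arange(n_env)  # guard against constant columns
        if np.any(vals.std(axis=0, ddof=1) == 0):
            return
        ec = ECMatrix([(f"l{i}", "1") for i in range(n_env)], vals,
                      [f"x{k}" for k in range(p)])
        s = standardize_ec(ec)
        assert np.allclose(s.values.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(s.values.std(axis=0, ddof=1), 1, atol=1e-10)


class TestMetMeans:
    def test_weight_validation(self):
        df = pd.DataFrame({"genotype": ["a"], "location": ["l"], "year": ["1"],
                           "mean": [4.0], "weight": [0.0]})
        with pytest.raises(FormatError, match="positive"):
            MetMeans(df)

    def test_filter_min_years(self):
        df = pd.DataFrame({
            "genotype": ["a", "a", "b"], "location": ["l", "l", "l"],
            "year": ["1", "2", "1"], "mean": [1.0, 2.0, 3.0],
            "weight": [1.0, 1.0, 1.0]})
        means = MetMeans(df).filter_min_years(2)
        assert means.genotypes() == ["a"]
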