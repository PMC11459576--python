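"""Group screens, prevalence, differential tests, gene-pair correlation."""

import numpy as np
import pandas as pd
import pytest

from steppanel.cohort_compare import (
    differential_by_group,
    gene_pair_correlation,
    high_mean_screen,
    prevalence_high,
)
from steppanel.errors import ConfigurationError, DegenerateInputError, SchemaError
from steppanel.normalization import ExpressionRatios

from conftest import make_sheet


def make_ratios(data: dict[str, list[float]], genes: list[str], histologies):
    """ExpressionRatios + sheet from a dict sample → ratio vector."""
    frame = pd.DataFrame(data, index=genes, dtype=float)
    sids = list(data)
    sheet = make_sheet(
        sids, ["B1"] * len(sids), [False] * len(sids), histologies=histologies
    )
    return ExpressionRatios(ratios=frame, reference_map={}), sheet


class TestHighMeanScreen:
    def test_boundary_arithmetic(self):
        ratios, sheet = make_ratios(
            {"a": [1.5, 1.5], "b": [0.4, 0.6]}, ["g_out", "g_in"], ["SCLC", "SCLC"]
        )
        hits = high_mean_screen(ratios, sheet, "SCLC")
        # means: g_out = 0.95 (excluded), g_in = 1.05 (included)
        assert hits["gene"].tolist() == ["g_in"]

    def test_single_sample_inclusion(self):
        ratios, sheet = make_ratios({"a": [1.2]}, ["g"], ["SCLC"])
        assert high_mean_screen(ratios, sheet, "SCLC")["gene"].tolist() == ["g"]

    def test_sorted_by_mean_descending(self):
        ratios, sheet = make_ratios(
            {"a": [1.0, 3.0, 2.0]}, ["g1", "g2", "g3"], ["SCLC"]
        )
        assert high_mean_screen(ratios, sheet, "SCLC")["gene"].tolist() == [
            "g2", "g3", "g1",
        ]

    def test_unknown_group_rejected(self):
        ratios, sheet = make_ratios({"a": [1.0]}, ["g"], ["SCLC"])
        with pytest.raises(ValueError):
            high_mean_screen(ratios, sheet, "LUAD")

    def test_recovery_of_truly_high_genes(self):
        # 26 genes at true mean 2.0 (SD 0.5) vs 100 null genes, n=35:
        # the screen should recover nearly all truly-high genes
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            genes = [f"hi{i}" for i in range(26)] + [f"null{i}" for i in range(100)]
            data = {
                f"s{j}": np.concatenate(
                    [rng.normal(2.0, 0.5, 26), rng.normal(0.0, 0.5, 100)]
                )
                for j in range(35)
            }
            ratios, sheet = make_ratios(data, genes, ["SCLC"] * 35)
            found = set(high_mean_screen(ratios, sheet, "SCLC")["gene"])
            if len(found & {f"hi{i}" for i in range(26)}) >= 24:
                hits += 1
        assert hits / n_seeds >= 0.9


class TestPrevalenceHigh:
    def test_printed_fraction(self):
        data = {f"s{i}": [2.0 if i < 32 else 0.0] for i in range(35)}
        ratios, sheet = make_ratios(data, ["DLL3"], ["SCLC"] * 35)
        count, n, frac = prevalence_high(ratios, sheet, "SCLC", "DLL3")
        assert (count, n) == (32, 35)
        assert frac == pytest.approx(32 / 35)

    def test_zero_prevalence(self):
        data = {f"s{i}": [-1.0] for i in range(5)}
        ratios, sheet = make_ratios(data, ["YAP1"], ["SCLC"] * 5)
        assert prevalence_high(ratios, sheet, "SCLC", "YAP1")[0] == 0

    def test_missing_gene_is_schema_error(self):
        ratios, sheet = make_ratios({"a": [1.0]}, ["g"], ["SCLC"])
        with pytest.raises(SchemaError):
            prevalence_high(ratios, sheet, "SCLC", "nope")


class TestDifferential:
    def _two_groups(self, a_vals, b_vals, genes=None):
        genes = genes or [f"g{i}" for i in range(len(a_vals[0]))]
        data = {}
        hist = []
        for i, v in enumerate(a_vals):
            data[f"a{i}"] = v
            hist.append("SCLC")
        for i, v in enumerate(b_vals):
            data[f"b{i}"] = v
            hist.append("LUAD")
        return make_ratios(data, genes, hist)

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        vals = [rng.normal(0, 1, 5) for _ in range(6)]
        ratios, sheet = self._two_groups(vals, vals)
        res = differential_by_group(ratios, sheet, "SCLC", "LUAD")
        assert (res["direction"] == "ns").all()
        assert (res["p"] > 0.9).all()

    def test_complete_separation(self):
        rng = np.random.default_rng(1)
        a = [rng.normal(3.0, 0.1, 4) for _ in range(10)]
        b = [rng.normal(0.0, 0.1, 4) for _ in range(10)]
        ratios, sheet = self._two_groups(a, b)
        res = differential_by_group(ratios, sheet, "SCLC", "LUAD")
        assert (res["p"] < 0.001).all()
        assert (res["direction"] == "higher_in_a").all()

    def test_swap_flips_direction_keeps_p(self):
        rng = np.random.default_rng(2)
        a = [rng.normal(1.0, 0.5, 6) for _ in range(8)]
        b = [rng.normal(-1.0, 0.5, 6) for _ in range(8)]
        ratios, sheet = self._two_groups(a, b)
        fwd = differential_by_group(ratios, sheet, "SCLC", "LUAD")
        rev = differential_by_group(ratios, sheet, "LUAD", "SCLC")
        np.testing.assert_allclose(fwd["p"], rev["p"])
        flipped = rev["direction"].replace(
            {"higher_in_a": "higher_in_b", "higher_in_b": "higher_in_a"}
        )
        assert (fwd["direction"] == flipped).all()

    def test_bh_is_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        a = [rng.normal(0.3, 1.0, 50) for _ in range(10)]
        b = [rng.normal(0.0, 1.0, 50) for _ in range(10)]
        ratios, sheet = self._two_groups(a, b)
        res = differential_by_group(ratios, sheet, "SCLC", "LUAD")
        assert (res["q"] >= res["p"] - 1e-12).all()
        assert (res["q"] <= 1.0 + 1e-12).all()
        ordered = res.sort_values("p")
        assert ordered["q"].is_monotonic_increasing

    def test_small_groups_rejected(self):
        ratios, sheet = self._two_groups([[1.0], [2.0]], [[0.0], [1.0], [2.0]])
        with pytest.raises(ConfigurationError):
            differential_by_group(ratios, sheet, "SCLC", "LUAD")


class TestGenePairCorrelation:
    def test_self_correlation(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1, 10)
        data = {f"s{i}": [vals[i], vals[i]] for i in range(10)}
        ratios, sheet = make_ratios(data, ["LAG3", "LAG3_copy"], ["SCLC"] * 10)
        c = gene_pair_correlation(ratios, sheet, "SCLC", "LAG3", "LAG3_copy")
        assert c.r == pytest.approx(1.0)

    def test_anticorrelation(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, 10)
        data = {f"s{i}": [vals[i], -vals[i]] for i in range(10)}
        ratios, sheet = make_ratios(data, ["g1", "g2"], ["SCLC"] * 10)
        assert gene_pair_correlation(ratios, sheet, "SCLC", "g1", "g2").r == pytest.approx(-1.0)

    def test_degenerate_variance(self):
        data = {f"s{i}": [1.0, float(i)] for i in range(5)}
        ratios, sheet = make_ratios(data, ["g1", "g2"], ["SCLC"] * 5)
        with pytest.raises(DegenerateInputError):
            gene_pair_correlation(ratios, sheet, "SCLC", "g1", "g2")

    def test_power_at_moderate_rank_correlation(self):
        # bivariate normal with correlation 0.6, n = 35: the null should be
        # rejected at α = 0.05 in at least 80% of replicates
        hits = 0
        n_seeds = 300
        cov = np.array([[1.0, 0.6], [0.6, 1.0]])
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            xy = rng.multivariate_normal([0, 0], cov, size=35)
            data = {f"s{i}": list(xy[i]) for i in range(35)}
            ratios, sheet = make_ratios(data, ["LAG3", "PDCD1"], ["SCLC"] * 35)
            c = gene_pair_correlation(ratios, sheet, "SCLC", "LAG3", "PDCD1")
            if c.p < 0.05:
                hits += 1
        assert hits / n_seeds >= 0.8
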