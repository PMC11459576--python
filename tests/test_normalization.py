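"""Normalization chain: background, control factors, geNorm, log2 ratios."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from steppanel.errors import ConfigurationError
from steppanel.normalization import (
    background_threshold,
    genorm_m_values,
    genorm_select,
    housekeeping_factors,
    log2_ratio_vs_reference,
    normalize,
    normalize_and_ratio,
    positive_factors,
)
from steppanel.panel_io import CountMatrix
from steppanel.synthetic_data import SimConfig, simulate_cohort

from conftest import make_sheet


def brute_force_m(log_expr: pd.DataFrame) -> pd.Series:
    """Naive double-loop geNorm stability oracle."""
    genes = list(log_expr.index)
    out = {}
    for j in genes:
        sds = [
            np.std(log_expr.loc[j] - log_expr.loc[k], ddof=1)
            for k in genes if k != j
        ]
        out[j] = float(np.mean(sds))
    return pd.Series(out)


class TestBackgroundThreshold:
    @pytest.mark.parametrize(
        "negatives,expected",
        [
            ([5, 5, 5, 5], 5.0),
            ([2, 4, 6, 8], 5.0 + 2.0 * np.std([2, 4, 6, 8], ddof=1)),  # ≈ 10.164
            ([0, 0], 0.0),
        ],
    )
    def test_mean_plus_two_sd(self, negatives, expected):
        assert background_threshold(negatives) == pytest.approx(expected, abs=1e-9)

    def test_requires_two_probes(self):
        with pytest.raises(ConfigurationError):
            background_threshold([7])


class TestPositiveFactors:
    def test_identical_samples_unit_factor(self, toy_cohort):
        counts = toy_cohort.counts.copy()
        counts["S1"] = counts["REF"]
        counts["S2"] = counts["REF"]
        cm = CountMatrix(counts=counts, panel=toy_cohort.panel, samples=toy_cohort.samples)
        assert np.allclose(positive_factors(cm), 1.0)

    def test_hand_example(self, small_panel):
        counts = pd.DataFrame(
            {"A": [10] * 9 + [100, 100, 100, 3, 3], "B": [10] * 9 + [400, 400, 400, 3, 3]},
            index=small_panel.genes,
        )
        sheet = make_sheet(["A", "B"], ["B1", "B1"], [True, False])
        cm = CountMatrix(counts=counts, panel=small_panel, samples=sheet)
        p = positive_factors(cm)
        assert p["A"] == pytest.approx(2.0)
        assert p["B"] == pytest.approx(0.5)

    def test_scale_equivariance(self, toy_cohort):
        p0 = positive_factors(toy_cohort)
        scaled = toy_cohort.counts.copy()
        scaled["S1"] = scaled["S1"] * 4
        cm = CountMatrix(counts=scaled, panel=toy_cohort.panel, samples=toy_cohort.samples)
        p1 = positive_factors(cm)
        # gm-1 constraint redistributes the change across all samples
        assert p1["S1"] / p0["S1"] == pytest.approx((1 / 4) * (4 ** (1 / 3)))

    def test_zero_positive_count_names_sample(self, toy_cohort):
        counts = toy_cohort.counts.copy()
        counts.loc["POS_C", "S2"] = 0
        cm = CountMatrix(counts=counts, panel=toy_cohort.panel, samples=toy_cohort.samples)
        with pytest.raises(ValueError, match="S2"):
            positive_factors(cm)


class TestGeNorm:
    example = pd.DataFrame(
        {
            "s1": [100, 50, 100],
            "s2": [200, 100, 100],
            "s3": [400, 200, 400],
        },
        index=["g1", "g2", "g3"],
    ).pipe(np.log2)

    def test_m_values_match_hand_computation(self):
        m = genorm_m_values(self.example)
        assert m["g1"] == pytest.approx(0.28868, abs=1e-4)
        assert m["g2"] == pytest.approx(0.28868, abs=1e-4)
        assert m["g3"] == pytest.approx(0.57735, abs=1e-4)

    def test_proportional_genes_zero_pair_sd(self):
        # g1 and g2 exactly proportional: their pairwise term is 0, so both
        # get identical M driven solely by g3
        m = genorm_m_values(self.example)
        assert m["g1"] == pytest.approx(m["g2"], abs=1e-12)

    def test_permuting_samples_leaves_m_unchanged(self):
        m0 = genorm_m_values(self.example)
        m1 = genorm_m_values(self.example[["s3", "s1", "s2"]])
        pd.testing.assert_series_equal(m0, m1)

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            x = pd.DataFrame(
                rng.normal(8, 1, size=(5, 8)),
                index=[f"g{i}" for i in range(5)],
            )
            fast = genorm_m_values(x)
            slow = brute_force_m(x)
            assert np.max(np.abs(fast - slow)) < 1e-10

    def test_elimination_starts_with_least_stable(self):
        res = genorm_select(self.example, min_housekeepers=2)
        assert res.elimination_order[0] == "g3"

    def test_all_proportional_selects_min_housekeepers(self):
        rng = np.random.default_rng(0)
        base = rng.normal(8, 1, size=10)
        x = pd.DataFrame(
            {f"g{i}": base + i * 0.5 for i in range(5)}
        ).T  # proportional on linear scale: constant log offsets
        x.columns = [f"s{j}" for j in range(10)]
        res = genorm_select(x, min_housekeepers=3)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in res.v_series.values())
        assert len(res.selected) == 3

    def test_stable_genes_recovered_from_noise(self):
        # 2 stable + 3 unstable candidates (10× SD ratio); the stable pair
        # must survive elimination in ≥95% of seeds
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            data = {
                "stable1": rng.normal(8.0, 0.05, 12),
                "stable2": rng.normal(9.0, 0.05, 12),
                "u1": rng.normal(8.0, 0.5, 12),
                "u2": rng.normal(7.0, 0.5, 12),
                "u3": rng.normal(8.5, 0.5, 12),
            }
            res = genorm_select(pd.DataFrame(data).T, min_housekeepers=2)
            if {"stable1", "stable2"} <= res.selected:
                hits += 1
        assert hits / n_seeds >= 0.95

    def test_too_few_candidates_rejected(self):
        with pytest.raises(ConfigurationError):
            genorm_m_values(self.example.iloc[:2])


class TestHousekeepingFactors:
    def test_identical_samples(self):
        counts = pd.DataFrame({"a": [100, 225], "b": [100, 225]}, index=["h1", "h2"])
        h = housekeeping_factors(counts, ["h1", "h2"])
        assert np.allclose(h, 1.0)

    def test_hand_example_cohort_gm(self):
        # per-sample housekeeping gms 100 and 225 → cohort gm 150
        counts = pd.DataFrame({"a": [100, 100], "b": [225, 225]}, index=["h1", "h2"])
        h = housekeeping_factors(counts, ["h1", "h2"])
        assert h["a"] == pytest.approx(1.5)
        assert h["b"] == pytest.approx(2 / 3)

    def test_doubling_housekeepers_halves_factor(self):
        counts = pd.DataFrame({"a": [100, 100], "b": [200, 200]}, index=["h1", "h2"])
        h = housekeeping_factors(counts, ["h1", "h2"])
        assert h["b"] / h["a"] == pytest.approx(0.5)


class TestNormalize:
    def test_single_sample_cohort_identity(self, small_panel):
        counts = pd.DataFrame(
            {"REF": [300, 200, 150, 80, 50, 40, 500, 400, 300, 640, 160, 40, 4, 6]},
            index=small_panel.genes,
        )
        sheet = make_sheet(["REF"], ["B1"], [True])
        cm = CountMatrix(counts=counts, panel=small_panel, samples=sheet)
        normalized, model = normalize(cm)
        assert model.pos_factor["REF"] == pytest.approx(1.0)
        assert model.hk_factor["REF"] == pytest.approx(1.0)
        b = model.background["REF"]
        expected = counts["REF"].astype(float).clip(lower=b)
        assert np.allclose(normalized["REF"], expected)

    def test_identical_samples_equal_floored_raw(self, toy_cohort):
        counts = toy_cohort.counts.copy()
        counts["S1"] = counts["REF"]
        counts["S2"] = counts["REF"]
        cm = CountMatrix(counts=counts, panel=toy_cohort.panel, samples=toy_cohort.samples)
        normalized, model = normalize(cm)
        for s in cm.sample_ids:
            b = model.background[s]
            assert np.allclose(normalized[s], counts[s].astype(float).clip(lower=b))

    def test_factor_geometric_means_are_one(self):
        cm, _ = simulate_cohort(SimConfig(n_samples=8, n_batches=2, seed=7))
        _, model = normalize(cm)
        assert np.exp(np.mean(np.log(model.pos_factor))) == pytest.approx(1.0, abs=1e-9)
        assert np.exp(np.mean(np.log(model.hk_factor))) == pytest.approx(1.0, abs=1e-9)


class TestLog2Ratio:
    def test_reference_vs_itself_exactly_zero(self, toy_cohort):
        ratios, _ = normalize_and_ratio(toy_cohort)
        assert (ratios.ratios["REF"] == 0.0).all()

    def test_closed_form_ratios(self, small_panel):
        # identical control probes → unit factors → pure count ratios
        counts = pd.DataFrame(
            {
                "REF": [100, 100, 100, 100, 100, 100, 200, 200, 200, 640, 160, 40, 0, 0],
                "S1": [400, 300, 100, 100, 100, 100, 200, 200, 200, 640, 160, 40, 0, 0],
            },
            index=small_panel.genes,
        )
        sheet = make_sheet(["REF", "S1"], ["B1", "B1"], [True, False])
        cm = CountMatrix(counts=counts, panel=small_panel, samples=sheet)
        ratios, _ = normalize_and_ratio(cm)
        assert ratios.ratios.at["ASCL1", "S1"] == pytest.approx(2.0)
        assert ratios.ratios.at["NEUROD1", "S1"] == pytest.approx(np.log2(3), abs=1e-9)

    def test_translation_free(self, small_panel):
        def ratios_for(scale):
            counts = pd.DataFrame(
                {
                    "REF": np.array([100, 100, 100, 100, 100, 100, 200, 200, 200,
                                     640, 160, 40, 4, 6]) * scale,
                    "S1": np.array([400, 300, 100, 100, 100, 100, 200, 200, 200,
                                    640, 160, 40, 4, 6]) * scale,
                },
                index=small_panel.genes,
            )
            sheet = make_sheet(["REF", "S1"], ["B1", "B1"], [True, False])
            cm = CountMatrix(counts=counts, panel=small_panel, samples=sheet)
            r, _ = normalize_and_ratio(cm)
            return r.ratios["S1"]

        pd.testing.assert_series_equal(ratios_for(1), ratios_for(8), atol=1e-9)

    def test_monotone_in_raw_count(self, toy_cohort):
        ratios0, _ = normalize_and_ratio(toy_cohort)
        bumped = toy_cohort.counts.copy()
        bumped.loc["ASCL1", "S1"] += 200
        cm = CountMatrix(counts=bumped, panel=toy_cohort.panel, samples=toy_cohort.samples)
        ratios1, _ = normalize_and_ratio(cm)
        assert ratios1.ratios.at["ASCL1", "S1"] >= ratios0.ratios.at["ASCL1", "S1"]

    @given(st.integers(min_value=101, max_value=100_000))
    @settings(
        deadline=None,
        max_examples=25,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    def test_ratio_matches_closed_form_for_any_count(self, small_panel, count):
        counts = pd.DataFrame(
            {
                "REF": [100, 100, 100, 100, 100, 100, 200, 200, 200, 640, 160, 40, 0, 0],
                "S1": [count, 100, 100, 100, 100, 100, 200, 200, 200, 640, 160, 40, 0, 0],
            },
            index=small_panel.genes,
        )
        sheet = make_sheet(["REF", "S1"], ["B1", "B1"], [True, False])
        cm = CountMatrix(counts=counts, panel=small_panel, samples=sheet)
        ratios, _ = normalize_and_ratio(cm)
        assert ratios.ratios.at["ASCL1", "S1"] == pytest.approx(
            np.log2(count / 100), abs=1e-9
        )
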