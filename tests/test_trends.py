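"""Quantile correction, fuzzy c-means, CI classifier of crossbred bias."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from ovimyo.synthetic import ExpressionSimSpec, make_count_matrix, study_design
from ovimyo.trends import (
    aggregate_bias_calls,
    call_bias,
    call_bias_matrix,
    classify_trend_patterns,
    confidence_interval,
    fcm_cluster,
    hypertrophy_gene_screen,
    normalize_to_normal,
    quantile_normalize,
    standardize_rows,
)


def _df(values, columns=None):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=columns or [f"s{j}" for j in range(values.shape[1])],
    )


class TestQuantileNormalize:
    def test_permuted_columns_become_identical_distributions(self, rng):
        base = rng.normal(size=40)
        m = _df(np.column_stack([base, rng.permutation(base), rng.permutation(base)]))
        out = quantile_normalize(m)
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        for j in range(1, 3):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0])

    def test_column_means_equal_after_correction(self, rng):
        m = _df(rng.gamma(2.0, 3.0, size=(100, 5)))
        out = quantile_normalize(m)
        means = out.mean(axis=0).to_numpy()
        np.testing.assert_allclose(means, means[0], rtol=1e-12)

    def test_single_sample_error(self):
        with pytest.raises(ValueError):
            quantile_normalize(_df([[1.0], [2.0]]))

    def test_corrected_nb_data_looks_normal_per_gene(self):
        spec = ExpressionSimSpec(
            n_genes=400, groups=[("H", "M3", 10)], nb_dispersion=0.3, seed=21
        )
        cm, _, _ = make_count_matrix(spec)
        corrected = normalize_to_normal(np.log2(cm.counts + 1.0), standardize=False)
        pvals = [
            scipy.stats.shapiro(corrected.iloc[i].to_numpy()).pvalue
            for i in range(200)
        ]
        # descriptive: no gross excess of rejections over the nominal rate
        assert np.mean(np.asarray(pvals) < 0.05) < 0.15

    def test_standardized_rows_zero_mean_unit_sd(self, rng):
        m = _df(rng.normal(size=(20, 6)))
        z = standardize_rows(m)
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1, atol=1e-12)


class TestFCM:
    def test_memberships_sum_to_one(self, rng):
        clust = fcm_cluster(rng.normal(size=(40, 5)), c=3, seed=1)
        np.testing.assert_allclose(
            clust.membership.sum(axis=1), 1.0, atol=1e-9
        )
        u = clust.membership.to_numpy()
        assert ((u >= 0) & (u <= 1)).all()
        assert np.isfinite(clust.centers).all()

    def test_objective_non_increasing(self, rng):
        clust = fcm_cluster(rng.normal(size=(60, 4)), c=4, seed=2)
        assert all(np.diff(clust.objective_history) <= 1e-9)

    def test_two_separated_trends_hard_assignment(self, rng):
        up = np.linspace(-1, 1, 4)
        x = np.vstack(
            [up + rng.normal(0, 0.1, 4) for _ in range(30)]
            + [-up + rng.normal(0, 0.1, 4) for _ in range(30)]
        )
        clust = fcm_cluster(x, c=2, seed=3)
        assert clust.membership.max(axis=1).min() > 0.95
        hard = clust.hard_assignment().to_numpy()
        assert len(set(hard[:30])) == 1 and len(set(hard[30:])) == 1
        assert hard[0] != hard[-1]

    def test_point_on_center_gets_full_membership(self):
        x = np.vstack([np.zeros((5, 2)), np.full((5, 2), 10.0)])
        clust = fcm_cluster(x, c=2, seed=4)
        np.testing.assert_allclose(clust.membership.max(axis=1), 1.0, atol=1e-12)

    def test_parameter_validation(self, rng):
        x = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            fcm_cluster(x, c=6)
        with pytest.raises(ValueError):
            fcm_cluster(x, c=1)
        with pytest.raises(ValueError):
            fcm_cluster(x, c=2, m=1.0)

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=(30, 4))
        a = fcm_cluster(x, c=3, seed=9)
        b = fcm_cluster(x, c=3, seed=9)
        pd.testing.assert_frame_equal(a.membership, b.membership)


class TestTrendPatterns:
    def _trends(self, rng, n_concordant=500, n_discordant=48, noise=0.2):
        stages = ["D3", "M3", "M6", "M12"]
        csa = {
            "H": np.array([1.0, 2.0, 2.1, 3.0]),
            "HD": np.array([1.0, 2.2, 3.0, 3.8]),
            "D": np.array([1.2, 2.5, 3.2, 4.0]),
        }
        n = n_concordant + n_discordant
        genes = [f"g{i}" for i in range(n)]
        trends = {}
        for breed in csa:
            base = (csa[breed] - csa[breed].mean()) / csa[breed].std()
            rows = []
            for i in range(n):
                sign = 1.0
                if i < n_discordant and breed == "D":
                    sign = -1.0  # anti-tracking in D only
                rows.append(sign * base + rng.normal(0, noise, 4))
            trends[breed] = pd.DataFrame(rows, index=genes, columns=stages)
        truth = np.array([i < n_discordant for i in range(n)])
        return trends, csa, truth

    def test_concordant_and_discordant_construction(self, rng):
        trends, csa, truth = self._trends(rng, n_concordant=40, n_discordant=8)
        result = classify_trend_patterns(trends, csa, seed=5)
        table = result.table
        # perfectly tracking genes are concordant with positive sign in H
        assert table.loc[~pd.Series(truth, index=table.index), "sign_H"].eq(1).mean() > 0.9

    def test_planted_discordant_recovered(self, rng):
        trends, csa, truth = self._trends(rng)
        result = classify_trend_patterns(trends, csa, seed=6)
        found = result.table["discordant"].to_numpy()
        sensitivity = found[truth].mean()
        assert sensitivity >= 0.9

    def test_mismatched_stage_grids_error(self, rng):
        trends, csa, _ = self._trends(rng, n_concordant=20, n_discordant=4)
        trends["D"] = trends["D"].rename(columns={"M12": "M24"})
        with pytest.raises(ValueError, match="stage grids"):
            classify_trend_patterns(trends, csa)


class TestConfidenceInterval:
    def test_constant_sample_zero_width(self):
        ci = confidence_interval([5, 5, 5, 5])
        assert (ci.lower, ci.mean, ci.upper) == (5.0, 5.0, 5.0)

    def test_two_point_closed_form(self):
        ci = confidence_interval([0.0, 2.0], level=0.95)
        assert ci.mean == pytest.approx(1.0)
        assert ci.upper == pytest.approx(1 + 12.706204736, abs=1e-3)
        assert ci.lower == pytest.approx(1 - 12.706204736, abs=1e-3)

    def test_nested_in_level(self, rng):
        x = rng.normal(size=10)
        narrow = confidence_interval(x, 0.95)
        wide = confidence_interval(x, 0.99)
        assert wide.lower < narrow.lower <= narrow.upper < wide.upper

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            confidence_interval([1.0])


class TestCallBias:
    def test_hd_at_d_mean_is_toward_d(self):
        bc = call_bias([0.0, 0.1, -0.1, 0.05], [10.0, 10.1, 9.9], 10.0)
        assert bc.call == "toward_D"

    def test_inside_both_intervals_unbiased(self):
        bc = call_bias([0.0, 1.0, 2.0], [0.5, 1.5, 2.5], 1.1)
        assert bc.call == "unbiased"

    def test_outside_both_goes_to_nearest_mean(self):
        bc = call_bias([0.0, 0.01, -0.01], [10.0, 10.01, 9.99], 7.0)
        assert bc.call == "toward_D"
        bc = call_bias([0.0, 0.01, -0.01], [10.0, 10.01, 9.99], 3.0)
        assert bc.call == "toward_H"

    def test_equidistant_tie_is_ambiguous(self):
        bc = call_bias([0.0, 0.01, -0.01], [10.0, 10.01, 9.99], 5.0)
        assert bc.call == "ambiguous"

    def test_pooled_mode(self):
        bc = call_bias(
            [0.0, 0.1, -0.1], [0.2, 0.3, 0.1], 0.15, mode="pooled_ci"
        )
        assert bc.call == "unbiased"
        bc = call_bias(
            [0.0, 0.1, -0.1], [0.2, 0.3, 0.1], 5.0, mode="pooled_ci"
        )
        assert bc.call == "toward_D"

    def test_affine_transform_leaves_calls_unchanged(self, rng):
        for _ in range(20):
            h = rng.normal(0, 1, 6)
            d = rng.normal(2, 1, 3)
            hd = float(rng.normal(1, 1))
            base = call_bias(h, d, hd).call
            shifted = call_bias(3.5 * h + 7, 3.5 * d + 7, 3.5 * hd + 7).call
            assert base == shifted

    def test_bias_count_monotone_in_level(self, rng):
        cases = [
            (rng.normal(0, 1, 6), rng.normal(1, 1, 3), float(rng.normal(0.5, 1)))
            for _ in range(50)
        ]
        counts = []
        for level in (0.5, 0.8, 0.95, 0.99):
            n_biased = sum(
                call_bias(h, d, hd, level=level).call != "unbiased"
                for h, d, hd in cases
            )
            counts.append(n_biased)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_insufficient_replicates_error(self):
        with pytest.raises(ValueError, match="H"):
            call_bias([1.0], [1.0, 2.0], 1.0)
        with pytest.raises(ValueError, match="D"):
            call_bias([1.0, 2.0], [1.0], 1.0)

    def test_vote_mode_majority(self):
        bc = call_bias(
            [0.0, 0.1, -0.1, 0.05], [10.0, 10.1, 9.9], [10.0, 9.95, 0.0],
            hd_summary="vote",
        )
        assert bc.call == "toward_D"

    def test_aggregate_majority_and_ties(self):
        a = call_bias([0, 0.1, -0.1], [10, 10.1, 9.9], 10.0)
        assert a.call == "toward_D"
        b = call_bias([0, 0.1, -0.1], [10, 10.1, 9.9], 0.0)
        assert b.call == "toward_H"
        assert aggregate_bias_calls([a, a, b]) == "toward_D"
        assert aggregate_bias_calls([a, b]) == "ambiguous"


class TestBiasPipeline:
    def test_planted_scenarios_recovered(self):
        scenarios = {}
        idx = 0
        for sc, n in (("toward_D", 30), ("toward_H", 30), ("unbiased", 40)):
            for _ in range(n):
                scenarios[idx] = sc
                idx += 1
        spec = ExpressionSimSpec(
            n_genes=1200, groups=study_design(), planted_bias=scenarios, seed=22
        )
        cm, sheet, truth = make_count_matrix(spec)
        corrected = quantile_normalize(np.log2(cm.counts + 1.0))
        table = call_bias_matrix(
            corrected, sheet, genes=list(truth["bias"]["gene_id"])
        )
        overall = table[table["stage"] == "overall"].set_index("gene_id")["call"]
        scen = truth["bias"].set_index("gene_id")["scenario"]
        assert (overall[scen == "toward_D"] == "toward_D").mean() >= 0.8
        assert (overall[scen == "toward_H"] == "toward_H").mean() >= 0.8
        false_bias = (
            overall[scen == "unbiased"].isin(["toward_D", "toward_H"]).mean()
        )
        assert false_bias <= 0.1


class TestHypertrophyScreen:
    def test_disjoint_inputs_empty(self):
        assert hypertrophy_gene_screen(
            [{"a", "b"}], {"green": {"c", "d"}}, "green"
        ) == []

    def test_degs_subset_of_module(self):
        out = hypertrophy_gene_screen(
            [{"a"}, {"b"}], {"green": {"a", "b", "c"}}, "green"
        )
        assert out == ["a", "b"]

    def test_hub_restriction_and_oracle(self, rng):
        genes = [f"g{i}" for i in range(20)]
        degs = set(rng.choice(genes, 8, replace=False))
        module = set(rng.choice(genes, 12, replace=False))
        hubs = set(rng.choice(sorted(module), 5, replace=False))
        out = hypertrophy_gene_screen([degs], {"m": module}, "m", hubs=hubs)
        assert out == sorted(degs & module & hubs)

    def test_unknown_module_error(self):
        with pytest.raises(ValueError, match="unknown module"):
            hypertrophy_gene_screen([{"a"}], {"green": {"a"}}, "blue")
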