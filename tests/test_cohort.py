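"""Stratification rules and survival statistics."""

import numpy as np
import pandas as pd
import pytest

from myeloniche.cohort import (
    composition_correlation,
    cox_hr,
    hierarchical_stratify,
    km_curve,
    logrank,
    median_split,
    presence_filter,
    signature_split,
)
from myeloniche.simulate import simulate_survival


def surv(times, events, groups):
    return pd.DataFrame({"time": times, "event": events, "group": groups})


class TestCompositionCorrelation:
    def test_identical_rows_r_one(self):
        P = pd.DataFrame([[0.5, 0.3, 0.2]] * 2 + [[0.1, 0.1, 0.8]], index=list("abc"))
        corr = composition_correlation(P)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        P = pd.DataFrame(rng.dirichlet([1] * 4, 10))
        corr = composition_correlation(P)
        assert np.allclose(corr.values, corr.values.T)
        assert np.allclose(np.diag(corr.values), 1.0)

    def test_archetypes_separate(self):
        rng = np.random.default_rng(1)
        archetypes = np.array([[20, 1, 1, 1], [1, 20, 1, 1], [1, 1, 1, 20]], dtype=float)
        rows, labels = [], []
        for k, alpha in enumerate(archetypes):
            rows.append(rng.dirichlet(alpha, 10))
            labels += [k] * 10
        P = pd.DataFrame(np.vstack(rows))
        corr = composition_correlation(P).values
        labels = np.array(labels)
        same = labels[:, None] == labels[None, :]
        off_diag = ~np.eye(30, dtype=bool)
        assert corr[same & off_diag].mean() > corr[~same].mean()

    def test_constant_row_excluded(self):
        P = pd.DataFrame([[0.25, 0.25, 0.25, 0.25], [0.7, 0.1, 0.1, 0.1], [0.1, 0.7, 0.1, 0.1], [0.1, 0.1, 0.7, 0.1]], index=list("abcd"))
        with pytest.warns(UserWarning, match="constant"):
            corr = composition_correlation(P)
        assert "a" not in corr.index


class TestHierarchicalStratify:
    def block_corr(self):
        names = [f"p{i}" for i in range(9)]
        corr = np.full((9, 9), 0.1)
        for blk in (slice(0, 3), slice(3, 6), slice(6, 9)):
            corr[blk, blk] = 0.9
        np.fill_diagonal(corr, 1.0)
        return pd.DataFrame(corr, index=names, columns=names)

    def test_blocks_recovered(self):
        strata = hierarchical_stratify(self.block_corr(), k=3)
        assert strata.nunique() == 3
        for blk in (["p0", "p1", "p2"], ["p3", "p4", "p5"], ["p6", "p7", "p8"]):
            assert strata[blk].nunique() == 1

    def test_k_equals_n_singletons(self):
        strata = hierarchical_stratify(self.block_corr(), k=9)
        assert strata.nunique() == 9

    def test_order_invariant_up_to_relabeling(self):
        corr = self.block_corr()
        perm = ["p4", "p0", "p8", "p2", "p6", "p1", "p5", "p3", "p7"]
        s1 = hierarchical_stratify(corr, 3)
        s2 = hierarchical_stratify(corr.loc[perm, perm], 3)
        # same partition: co-membership matrices agree
        m1 = {p: s1[p] for p in corr.index}
        m2 = {p: s2[p] for p in corr.index}
        for a in corr.index:
            for b in corr.index:
                assert (m1[a] == m1[b]) == (m2[a] == m2[b])

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_stratify(self.block_corr(), k=10)


class TestSplits:
    def test_median_split_strict_rule(self):
        P = pd.DataFrame({"S": [0.1, 0.2, 0.3, 0.4]}, index=list("abcd"))
        labels = median_split(P, ["S"])
        assert list(labels) == ["low", "low", "high", "high"]

    def test_median_split_odd_n(self):
        P = pd.DataFrame({"S": [1.0, 2.0, 3.0]})
        labels = median_split(P, ["S"])
        assert list(labels) == ["low", "low", "high"]

    def test_median_split_all_equal_warns_all_low(self):
        P = pd.DataFrame({"S": [0.5, 0.5, 0.5]})
        with pytest.warns(UserWarning, match="median"):
            labels = median_split(P, ["S"])
        assert (labels == "low").all()

    def test_median_split_combines_subtypes(self):
        P = pd.DataFrame({"S1": [0.1, 0.4], "S2": [0.1, 0.0]})
        labels = median_split(P, ["S1", "S2"])
        assert list(labels) == ["low", "high"]

    def test_empty_subtype_list_rejected(self):
        with pytest.raises(ValueError):
            median_split(pd.DataFrame({"S": [1.0]}), [])

    def test_presence_filter_drops_zero_abundance(self):
        P = pd.DataFrame({"S1": [0.0, 0.2], "S2": [0.0, 0.1]}, index=["absent", "present"])
        with pytest.warns(UserWarning, match="zero estimated"):
            kept = presence_filter(P, ["S1", "S2"])
        assert list(kept.index) == ["present"]

    def test_signature_split_single_gene_is_median_split(self):
        rng = np.random.default_rng(0)
        bulk = pd.DataFrame({"GENE": rng.lognormal(0, 1, 20)})
        labels, score, _ = signature_split(bulk, ["GENE"])
        assert (labels == np.where(bulk["GENE"] > bulk["GENE"].median(), "high", "low")).all()

    def test_signature_split_scale_equivariant(self):
        rng = np.random.default_rng(1)
        bulk = pd.DataFrame(rng.lognormal(0, 1, (30, 5)), columns=list("abcde"))
        l1, _, _ = signature_split(bulk, ["a", "b"])
        l2, _, _ = signature_split(bulk * 2, ["a", "b"])
        assert l1.equals(l2)

    def test_signature_split_planted_subgroup(self):
        rng = np.random.default_rng(2)
        bulk = pd.DataFrame(rng.normal(10, 1, (40, 10)))
        bulk.columns = [f"g{i}" for i in range(10)]
        bulk.iloc[:10] += 5.0  # shift the signature sum far above the rest
        # pick the cutoff from the score histogram, as the widest empty gap
        _, score, hist = signature_split(bulk, [f"g{i}" for i in range(10)])
        counts, edges = hist
        gap = np.flatnonzero(counts == 0)
        cutoff = edges[gap[len(gap) // 2]]
        labels, _, _ = signature_split(bulk, [f"g{i}" for i in range(10)], cutoff=cutoff)
        assert (labels.iloc[:10] == "high").all()
        assert (labels.iloc[10:] == "low").all()
        assert counts.sum() == 40

    def test_signature_split_no_genes_rejected(self):
        with pytest.raises(ValueError):
            signature_split(pd.DataFrame({"a": [1.0]}), ["zzz"])


class TestKaplanMeier:
    def test_uncensored_equals_empirical_survival(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        t = surv(times, [1] * 5, ["g"] * 5)
        curve = km_curve(t, "g")
        for time, s in zip(curve["time"], curve["survival"]):
            expected = np.mean(np.array(times) > time)
            assert s == pytest.approx(expected)

    def test_single_subject_step(self):
        curve = km_curve(surv([5.0], [1], ["g"]), "g")
        assert list(curve["time"]) == [0.0, 5.0]
        assert list(curve["survival"]) == [1.0, 0.0]

    def test_all_censored_stays_at_one(self):
        curve = km_curve(surv([1.0, 2.0], [0, 0], ["g"] * 2), "g")
        assert (curve["survival"] == 1.0).all()

    def test_nonincreasing_starts_at_one(self):
        t = simulate_survival(100, {"g": 0.2}, censor_rate=0.05, seed=0)
        curve = km_curve(t, "g")
        assert curve["survival"].iloc[0] == 1.0
        assert (np.diff(curve["survival"]) <= 1e-12).all()


class TestLogrank:
    def test_two_subject_hand_calculation(self):
        # A: event at t=1; B: event at t=2 -> O_A - E_A = 0.5, Var = 0.25
        chi2, p = logrank(surv([1.0, 2.0], [1, 1], ["A", "B"]))
        assert chi2 == pytest.approx(1.0)

    def test_identical_groups_chi2_zero(self):
        t = surv([1.0, 2.0, 3.0] * 2, [1, 1, 0] * 2, ["A"] * 3 + ["B"] * 3)
        chi2, p = logrank(t)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_relabeling_invariance(self):
        t = simulate_survival(50, {"x": 0.1, "y": 0.3}, censor_rate=0.05, seed=0)
        chi2a, _ = logrank(t)
        swapped = t.assign(group=t["group"].map({"x": "y", "y": "x"}))
        chi2b, _ = logrank(swapped)
        assert chi2a == pytest.approx(chi2b)

    def test_null_p_roughly_uniform(self):
        pvals = [
            logrank(simulate_survival(60, {"a": 0.1, "b": 0.1}, censor_rate=0.02, seed=s))[1]
            for s in range(100)
        ]
        frac = np.mean(np.array(pvals) < 0.05)
        assert frac <= 0.12

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            logrank(surv([1.0, 2.0], [0, 0], ["A", "B"]))


class TestCox:
    def test_true_hr_two_recovered(self):
        t = simulate_survival(500, {"low": 0.1, "high": 0.2}, censor_rate=0.02, seed=0)
        hr, ci, p = cox_hr(t, reference_group="low")
        assert 1.6 <= hr <= 2.5
        assert ci[0] <= 2.0 <= ci[1]
        assert p < 0.05

    def test_identical_hazards_hr_near_one(self):
        t = simulate_survival(500, {"a": 0.1, "b": 0.1}, censor_rate=0.02, seed=1)
        hr, ci, p = cox_hr(t, reference_group="a")
        assert 0.8 <= hr <= 1.25
        assert p > 0.05

    def test_group_swap_inverts_hr(self):
        t = simulate_survival(200, {"a": 0.1, "b": 0.3}, censor_rate=0.02, seed=2)
        hr_ab, _, _ = cox_hr(t, reference_group="a")
        hr_ba, _, _ = cox_hr(t, reference_group="b")
        assert hr_ab == pytest.approx(1.0 / hr_ba, rel=1e-6)

    def test_matches_lifelines_on_tie_free_data(self):
        from lifelines import CoxPHFitter

        t = simulate_survival(150, {"a": 0.1, "b": 0.25}, censor_rate=0.05, seed=3)
        hr, ci, p = cox_hr(t, reference_group="a")
        cph = CoxPHFitter()
        df = t.assign(x=(t["group"] == "b").astype(float))[["time", "event", "x"]]
        cph.fit(df, duration_col="time", event_col="event")
        # continuous times: no ties, so Breslow and Efron coincide
        assert hr == pytest.approx(float(np.exp(cph.params_["x"])), rel=1e-5)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            cox_hr(surv([1.0, 2.0], [1, 1], ["a", "a"]), reference_group="a")

    def test_group_without_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            cox_hr(surv([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 0], ["a", "a", "b", "b"]), "a")

    def test_ci_coverage_at_true_hr_two(self):
        covered = 0
        n_rep = 100
        for r in range(n_rep):
            t = simulate_survival(500, {"low": 0.1, "high": 0.2}, censor_rate=0.02, seed=10_000 + r)
            _, ci, _ = cox_hr(t, reference_group="low")
            covered += ci[0] <= 2.0 <= ci[1]
        assert covered / n_rep >= 0.9
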