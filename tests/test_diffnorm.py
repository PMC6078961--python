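import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from metaquin.diffnorm import (
    benjamini_hochberg,
    diff_test,
    group_cv,
    normalize_absolute,
    normalize_conventional,
    observed_lfc,
    rle_summary,
    roc_curve,
    ruv_normalize,
    sequin_read_fraction,
    upper_quartile_factors,
)
from metaquin.mixtures import ROLE_EQUIMOLAR, ROLE_FOLD_CHANGE


def frame(data, samples=None):
    df = pd.DataFrame(data)
    if samples:
        df.columns = samples
    return df


class TestObservedLfc:
    def test_identical_groups_zero(self):
        counts = frame({"a1": [10, 5], "a2": [10, 5], "b1": [10, 5],
                        "b2": [10, 5]})
        res = observed_lfc(counts, ["a1", "a2"], ["b1", "b2"])
        assert (res["observed_lfc"] == 0).all()

    def test_doubled_group(self):
        counts = frame({"a": [10, 10], "b": [20, 20]})
        res = observed_lfc(counts, ["a"], ["b"], normalize=False)
        assert (res["observed_lfc"] == 1.0).all()

    def test_hand_computed_means(self):
        counts = frame({"a1": [10], "a2": [20], "b1": [40], "b2": [40]})
        res = observed_lfc(counts, ["a1", "a2"], ["b1", "b2"], normalize=False)
        assert res["observed_lfc"].iloc[0] == pytest.approx(np.log2(40 / 15))

    def test_zero_mean_flagged_missing(self):
        counts = frame({"a1": [0, 5], "a2": [0, 5], "b1": [3, 5], "b2": [1, 5]})
        res = observed_lfc(counts, ["a1", "a2"], ["b1", "b2"])
        assert res["missing"].iloc[0] and np.isnan(res["observed_lfc"].iloc[0])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="at least one sample"):
            observed_lfc(frame({"a": [1]}), [], ["a"])


class TestBenjaminiHochberg:
    def test_hand_computed_case(self):
        adj = benjamini_hochberg(np.array([0.01, 0.02, 0.04, 0.05]))
        assert adj == pytest.approx([0.04, 0.04, 0.05, 0.05])

    @settings(deadline=None, derandomize=True)
    @given(
        hnp.arrays(
            float,
            st.integers(1, 30),
            elements=st.floats(1e-8, 1.0),
        )
    )
    def test_properties(self, p):
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in rank


class TestDiffTest:
    def test_identical_replicates_full_specificity(self):
        counts = frame(
            {s: [100, 50, 10] for s in ["a1", "a2", "b1", "b2"]}
        )
        roles = {0: ROLE_EQUIMOLAR, 1: ROLE_EQUIMOLAR, 2: ROLE_EQUIMOLAR}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = diff_test(counts, ["a1", "a2"], ["b1", "b2"], roles=roles)
        assert (res.table["p"] == 1.0).all()
        assert res.specificity == 1.0

    def test_strong_change_detected(self):
        rng = np.random.default_rng(0)
        base = np.array([1000.0, 500.0, 200.0])
        cols = {}
        for r in range(3):
            cols[f"a{r}"] = rng.poisson(base)
            cols[f"b{r}"] = rng.poisson(base * [8.0, 1.0, 1.0])
        counts = frame(cols)
        roles = {0: ROLE_FOLD_CHANGE, 1: ROLE_EQUIMOLAR, 2: ROLE_EQUIMOLAR}
        res = diff_test(counts, ["a0", "a1", "a2"], ["b0", "b1", "b2"],
                        roles=roles)
        assert res.table["significant"].iloc[0]
        assert res.sensitivity == 1.0

    def test_requires_replication(self):
        with pytest.raises(ValueError, match="2 replicates"):
            diff_test(frame({"a": [1], "b": [2]}), ["a"], ["b"])


class TestRoc:
    def test_perfect_separation(self):
        res = roc_curve([0.001, 0.002, 0.8, 0.9], [True, True, False, False])
        assert res.auc == 1.0

    def test_all_tied_gives_diagonal(self):
        res = roc_curve([0.5] * 6, [True, False] * 3)
        assert res.auc == 0.5
        assert len(res.fpr) == 2  # single simultaneous step

    def test_enumerated_example(self):
        assert roc_curve([0.01, 0.2, 0.3, 0.4], [1, 1, 0, 0]).auc == 1.0
        assert roc_curve([0.01, 0.2, 0.3, 0.4], [1, 0, 1, 0]).auc == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            roc_curve([0.1, 0.2], [True, True])

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 1000))
    def test_auc_equals_mann_whitney_oracle(self, seed):
        """AUC equals the normalized pair-count (Mann-Whitney) statistic,
        counting ties as half, including with duplicated scores."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = rng.integers(0, 10, n) / 10.0  # deliberately tied
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            return
        pos = scores[labels]
        neg = scores[~labels]
        wins = sum(
            1.0 if p < q else 0.5 if p == q else 0.0
            for p, q in itertools.product(pos, neg)
        )
        oracle = wins / (len(pos) * len(neg))
        assert roc_curve(scores, labels).auc == pytest.approx(oracle)


class TestConventionalNormalization:
    def test_size_weighted_fractions(self):
        counts = frame({"s1": [10, 10]})
        res = normalize_conventional(counts, {0: 2.0, 1: 1.0})
        assert res["s1"].to_numpy() == pytest.approx([1 / 3, 2 / 3])

    def test_invariant_to_total_load(self):
        """Scaling any sample's counts leaves its fractions unchanged --
        relative abundance cannot see absolute load."""
        rng = np.random.default_rng(1)
        counts = frame({"s1": rng.integers(1, 100, 5),
                        "s2": rng.integers(1, 100, 5)})
        sizes = {i: float(rng.integers(1, 10)) for i in range(5)}
        scaled = counts.copy()
        scaled["s1"] *= 7
        scaled["s2"] *= 3
        a = normalize_conventional(counts, sizes)
        b = normalize_conventional(scaled, sizes)
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_single_feature_fraction_one(self):
        res = normalize_conventional(frame({"s": [42]}), {0: 5.0})
        assert res["s"].iloc[0] == 1.0


class TestSequinFraction:
    def test_simple_fraction(self):
        counts = pd.DataFrame({"s1": [100, 9900]}, index=["sq", "comm"])
        phi = sequin_read_fraction(counts, ["sq"])
        assert phi["s1"] == 0.01

    def test_all_sequin_rejected(self):
        counts = pd.DataFrame({"s1": [100]}, index=["sq"])
        with pytest.raises(ValueError, match="community"):
            sequin_read_fraction(counts, ["sq"])

    def test_fixed_spike_fraction_halves_with_doubled_community(self):
        # community reads double, spike constant: phi ~ m/(m+M) halves-ish
        counts = pd.DataFrame(
            {"low": [100, 900], "high": [100, 1900]}, index=["sq", "comm"]
        )
        phi = sequin_read_fraction(counts, ["sq"])
        assert phi["low"] == 0.1 and phi["high"] == 0.05


class TestAbsoluteNormalization:
    def test_halved_phi_doubles_index(self):
        frac = frame({"s1": [0.5, 0.5], "s2": [0.5, 0.5]})
        phi = pd.Series({"s1": 0.1, "s2": 0.05})
        res = normalize_absolute(frac, phi)
        assert np.allclose(res["s2"], 2 * res["s1"])

    def test_zero_phi_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            normalize_absolute(frame({"s1": [0.5]}), pd.Series({"s1": 0.0}))


class TestRuv:
    def test_k0_identity(self):
        logc = frame({"s1": [1.0, 2.0, 3.0], "s2": [2.0, 1.0, 4.0]})
        adjusted, w = ruv_normalize(logc, [0, 1], k=0)
        assert adjusted.equals(logc)
        assert w.shape == (2, 0)

    def test_constant_offset_removed(self):
        """Two samples whose control log-counts differ by a constant are
        equalized on controls after k=1 (rank-1 algebra)."""
        rng = np.random.default_rng(2)
        base = rng.normal(5, 1, 10)
        logc = pd.DataFrame(
            {"s1": base, "s2": base + 0.7, "s3": base - 0.3},
            index=[f"f{i}" for i in range(10)],
        )
        controls = [f"f{i}" for i in range(6)]
        adjusted, w = ruv_normalize(logc, controls, k=1)
        ctl = adjusted.loc[controls]
        assert np.allclose(ctl["s1"], ctl["s2"], atol=1e-8)
        assert np.allclose(ctl["s1"], ctl["s3"], atol=1e-8)

    def test_rank_one_sample_effect_removed_everywhere(self):
        """A sample-wise offset applied to ALL features is a rank-1
        perturbation; k=1 removes essentially all control variance."""
        rng = np.random.default_rng(3)
        clean = pd.DataFrame(
            np.tile(rng.normal(6, 1, 20)[:, None], (1, 4)),
            index=[f"f{i}" for i in range(20)],
            columns=list("abcd"),
        )
        offsets = pd.Series([0.0, 1.1, -0.4, 0.6], index=list("abcd"))
        dirty = clean.add(offsets, axis=1)
        controls = [f"f{i}" for i in range(8)]
        before = dirty.loc[controls].var(axis=1).sum()
        adjusted, _ = ruv_normalize(dirty, controls, k=1)
        after = adjusted.loc[controls].var(axis=1).sum()
        assert after <= 1e-8 * before

    def test_k_too_large_rejected(self):
        logc = frame({"s1": [1.0, 2.0], "s2": [2.0, 1.0]})
        with pytest.raises(ValueError, match="smaller"):
            ruv_normalize(logc, [0, 1], k=2)


class TestRleCvUq:
    def test_identical_samples_rle_zero(self):
        counts = frame({s: [10, 20, 30] for s in "abc"})
        rle = rle_summary(counts)
        assert (rle["median"] == 0).all()

    def test_cv_examples(self):
        values = frame({"r1": [2.0, 1.0], "r2": [2.0, 2.0], "r3": [2.0, 3.0]})
        cv = group_cv(values, {"g": ["r1", "r2", "r3"]})
        assert cv.loc[0, "g"] == 0.0
        assert cv.loc[1, "g"] == pytest.approx(0.5)  # sample SD 1, mean 2

    def test_cv_needs_replicates(self):
        with pytest.raises(ValueError, match="replicates"):
            group_cv(frame({"r1": [1.0]}), {"g": ["r1"]})

    def test_upper_quartile(self):
        counts = frame({"s": [0, 1, 2, 3, 4]})
        assert upper_quartile_factors(counts)["s"] == pytest.approx(3.25)
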