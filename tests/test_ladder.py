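import math

import numpy as np
import pytest

from metaquin.ladder import (
    annotate_homopolymers,
    bias_profile,
    coverage_summary,
    detection_limits,
    error_rate_report,
    fit_ladder,
    fit_richards,
    n50,
    welch_t_test,
)
from metaquin.mixtures import MixtureEntry, MixtureSpec, build_ladder
from metaquin.simulate import Placements, compose_sample, simulate_short_reads

from conftest import make_sequins


def placements_from_tuples(rows, ref_names):
    """rows: (ref_name, start, end, strand)"""
    idx = {n: i for i, n in enumerate(ref_names)}
    return Placements(
        list(ref_names),
        np.array([idx[r[0]] for r in rows], dtype=np.int32),
        np.array([r[1] for r in rows], dtype=np.int64),
        np.array([r[2] for r in rows], dtype=np.int64),
        np.array([r[3] for r in rows], dtype=np.int8),
    )


def brute_force_coverage(rows, length):
    depth = np.zeros(length)
    for _, s, e, _ in rows:
        depth[s:e] += 1
    return depth


class TestCoverageSummary:
    def test_single_read(self):
        pl = placements_from_tuples([("r", 0, 100, 1)], ["r"])
        cov = coverage_summary(pl, {"r": 1000})
        row = cov["r"]
        assert row.mean_depth == 0.1
        assert row.breadth == 0.1
        assert row.read_count == 1 and row.detected

    def test_overlapping_reads(self):
        pl = placements_from_tuples([("r", 0, 100, 1), ("r", 50, 150, -1)], ["r"])
        row = coverage_summary(pl, {"r": 1000})["r"]
        assert row.mean_depth == 0.2
        assert row.breadth == 0.15

    def test_no_reads_undetected(self):
        pl = placements_from_tuples([], ["r"])
        row = coverage_summary(pl, {"r": 500})["r"]
        assert not row.detected and row.breadth == 0.0 and row.mean_depth == 0.0

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(3)
        length = 2000
        rows = []
        for _ in range(300):
            s = int(rng.integers(0, length - 50))
            e = s + int(rng.integers(10, 51))
            rows.append(("r", s, e, 1 if rng.random() < 0.5 else -1))
        cov = coverage_summary(placements_from_tuples(rows, ["r"]), {"r": length})
        depth = brute_force_coverage(rows, length)
        assert cov["r"].mean_depth == pytest.approx(depth.mean())
        assert cov["r"].breadth == pytest.approx((depth > 0).mean())

    def test_unknown_ref_rejected(self):
        pl = placements_from_tuples([("x", 0, 10, 1)], ["x"])
        with pytest.raises(ValueError, match="unknown reference ids: x"):
            coverage_summary(pl, {"r": 100})

    def test_sam_input(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:r\tLN:1000\n"
            "a\t0\tr\t1\t60\t100M\t*\t0\t0\t" + "A" * 100 + "\t*\n"
            "b\t16\tr\t51\t60\t100M\t*\t0\t0\t" + "A" * 100 + "\t*\n"
            "c\t4\t*\t0\t0\t*\t*\t0\t0\tAAAA\t*\n"  # unmapped: ignored
            "d\t256\tr\t1\t60\t100M\t*\t0\t0\t*\t*\n"  # secondary: ignored
        )
        cov = coverage_summary(str(sam), {"r": 1000})
        assert cov["r"].read_count == 2
        assert cov["r"].mean_depth == 0.2
        assert cov["r"].breadth == 0.15


def ladder_with_depths(depths):
    """Five-sequin toy ladder plus a coverage table with given mean depths."""
    sequins = make_sequins(5, seed=1)
    mix = build_ladder(sequins, n_points=5, dilution=2.0, anchor=1.0)
    import pandas as pd

    conc = mix.concentrations
    ids = [e.sequin_id for e in mix.entries]
    table = pd.DataFrame(
        {
            "read_count": [1 if depths[i] > 0 else 0 for i in ids],
            "mean_depth": [depths[i] for i in ids],
            "breadth": [min(1.0, depths[i]) for i in ids],
            "detected": [depths[i] > 0 for i in ids],
        },
        index=pd.Index(ids, name="ref_id"),
    )
    from metaquin.ladder import CoverageSummary

    return CoverageSummary(table), mix, conc


class TestFitLadder:
    def test_exact_proportionality(self):
        sequins = make_sequins(8, seed=2)
        mix = build_ladder(sequins, n_points=4, anchor=2.0)
        import pandas as pd

        from metaquin.ladder import CoverageSummary

        conc = mix.concentrations
        table = pd.DataFrame(
            {
                "read_count": 10,
                "mean_depth": [0.37 * conc[i] for i in conc],
                "breadth": 1.0,
                "detected": True,
            },
            index=pd.Index(list(conc), name="ref_id"),
        )
        fit = fit_ladder(CoverageSummary(table), mix)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.n_used == 8 and fit.excluded == ()

    def test_hand_computed_ols(self):
        """Closed-form OLS on (0,0),(1,1.1),(2,1.9),(3,3.0):
        Sxy=4.9, Sxx=5, Syy=4.82 -> slope 0.98, intercept 0.03,
        r^2 = 4.9^2/(5*4.82)."""
        sequins = make_sequins(4, seed=3)
        mix = build_ladder(sequins, n_points=4, dilution=2.0, anchor=1.0)
        import pandas as pd

        from metaquin.ladder import CoverageSummary

        # ladder log2 concentrations are 3,2,1,0 per point
        ys = {0: 3.0, 1: 1.9, 2: 1.1, 3: 0.0}
        ids, depths = [], []
        for e in mix.entries:
            ids.append(e.sequin_id)
            depths.append(2.0 ** ys[e.point_index])
        table = pd.DataFrame(
            {"read_count": 1, "mean_depth": depths, "breadth": 1.0,
             "detected": True},
            index=pd.Index(ids, name="ref_id"),
        )
        fit = fit_ladder(CoverageSummary(table), mix)
        assert fit.slope == pytest.approx(0.98, abs=1e-12)
        assert fit.intercept == pytest.approx(0.03, abs=1e-12)
        assert fit.r_squared == pytest.approx(4.9**2 / (5 * 4.82), abs=1e-12)

    def test_constant_depth_gives_zero_slope(self):
        cov, mix, _ = ladder_with_depths(
            {f"MG_0{i}": 1.0 for i in range(1, 6)}
        )
        assert fit_ladder(cov, mix).slope == pytest.approx(0.0, abs=1e-12)

    def test_zero_coverage_excluded(self):
        depths = {f"MG_0{i}": 0.0 for i in range(1, 6)}
        for i in (1, 2, 3):
            depths[f"MG_0{i}"] = 2.0 ** (5 - i)
        cov, mix, conc = ladder_with_depths(depths)
        fit = fit_ladder(cov, mix)
        assert fit.n_used == 3 and len(fit.excluded) == 2

    def test_too_few_points(self):
        depths = {f"MG_0{i}": 0.0 for i in range(1, 6)}
        depths["MG_01"] = 1.0
        depths["MG_02"] = 2.0
        cov, mix, _ = ladder_with_depths(depths)
        with pytest.raises(ValueError, match="fewer than 3"):
            fit_ladder(cov, mix)


@pytest.fixture(scope="module")
def ladder16(sequins86):
    return build_ladder(sequins86)


class TestDetectionLimits:
    @staticmethod
    def coverage_for(mix, undetected_points=()):
        import pandas as pd

        from metaquin.ladder import CoverageSummary

        rows = {}
        for e in mix.entries:
            hit = e.point_index not in undetected_points
            rows[e.sequin_id] = {
                "read_count": 5 if hit else 0,
                "mean_depth": 0.5 if hit else 0.0,
                "breadth": 0.5 if hit else 0.0,
                "detected": hit,
            }
        return CoverageSummary(pd.DataFrame(rows).T)

    def test_all_detected_dynamic_range(self, ladder16):
        det = detection_limits(self.coverage_for(ladder16), ladder16)
        assert det.n_detected == 86
        assert det.lod == 60.0
        assert det.dynamic_range == 2**15 == 32768

    def test_bottom_point_undetected(self, ladder16):
        det = detection_limits(
            self.coverage_for(ladder16, undetected_points={15}), ladder16
        )
        assert det.lod == 120.0
        assert det.dynamic_range == 2**14 == 16384

    def test_top_point_undetected_is_flagged(self, ladder16):
        det = detection_limits(
            self.coverage_for(ladder16, undetected_points={0}), ladder16
        )
        assert det.lod is None and det.dynamic_range is None
        assert "undefined" in det.flagged


class TestBiasProfile:
    def test_single_sequin_normalizes_to_one(self):
        sequins = make_sequins(2, seed=5)
        mix = build_ladder(sequins, n_points=2, anchor=1.0)
        import pandas as pd

        from metaquin.ladder import CoverageSummary

        conc = mix.concentrations
        table = pd.DataFrame(
            {
                "read_count": 1,
                "mean_depth": [3.0 * conc[i] for i in conc],
                "breadth": 1.0,
                "detected": True,
            },
            index=pd.Index(list(conc), name="ref_id"),
        )
        profile = bias_profile(CoverageSummary(table), mix, "gc")
        assert profile.table["obs_over_exp"].to_numpy() == pytest.approx(
            [1.0, 1.0]
        )
        assert list(profile.table["gc"]) == sorted(profile.table["gc"])

    def test_unbiased_simulation_close_to_flat(self):
        """obs/exp coverage from an unbiased simulation stays within the
        pair-level Poisson bound of 1 at every ladder point."""
        sequins = make_sequins(20, seed=6)
        mix = build_ladder(sequins, n_points=4)  # shallow ladder: all points deep
        lengths = {s.id: s.length for s in sequins}
        spec = compose_sample([], mixture=mix, sequin_lengths=lengths)
        rs = simulate_short_reads(spec, 200000, seed=6, emit="placements_only")
        cov = coverage_summary(rs.placements, lengths)
        profile = bias_profile(cov, mix, "gc")
        counts = cov.table["read_count"]
        for _, row in profile.table.iterrows():
            n_pairs = counts[row["ref_id"]] / 2  # mates share the fragment
            se = row["obs_over_exp"] / math.sqrt(n_pairs)
            assert abs(row["obs_over_exp"] - 1.0) <= 4 * se


class TestAnnotateHomopolymers:
    @pytest.mark.parametrize(
        "seq,min_len,expected",
        [
            ("AAAAA", 6, []),
            ("ACGTAAAAAAGT", 6, [(4, 10)]),
            ("GGGGGGG", 6, [(0, 7)]),
            ("AACCCGGGGTTTTT", 3, [(2, 5), (5, 9), (9, 14)]),
        ],
    )
    def test_examples(self, seq, min_len, expected):
        assert annotate_homopolymers(seq, min_len) == expected


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_hand_computed_case(self):
        t, df, p = welch_t_test([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.224744871, abs=1e-8)
        assert df == pytest.approx(4.0)

    def test_antisymmetry(self):
        t1, _, p1 = welch_t_test([1, 2, 3], [5, 6, 9])
        t2, _, p2 = welch_t_test([5, 6, 9], [1, 2, 3])
        assert t1 == -t2 and p1 == p2

    def test_degenerate_variance(self):
        with pytest.warns(UserWarning, match="degenerate"):
            t, df, p = welch_t_test([2, 2, 2], [2, 2, 2])
        assert t == 0.0 and p == 1.0


class TestErrorRateReport:
    def test_error_free_rates_zero(self):
        ref = "ACGT" * 2000
        spec = compose_sample([("r", ref, 1.0)])
        rs = simulate_short_reads(spec, 500, seed=1, emit="fastq")
        report = error_rate_report(rs.placements, {"r": ref})
        assert report.mismatch_rate == 0.0
        assert report.insertion_rate == 0.0
        assert report.deletion_rate == 0.0

    def test_mismatch_rate_recovery(self):
        rng = np.random.default_rng(2)
        ref = "".join(np.array(list("ACGT"))[rng.choice(4, 20000)])
        spec = compose_sample([("r", ref, 1.0)])
        from metaquin.simulate import ErrorModel

        rs = simulate_short_reads(spec, 4000, ErrorModel(mismatch_rate=0.01),
                                  seed=3)
        report = error_rate_report(rs.placements, {"r": ref})
        se = math.sqrt(0.01 * 0.99 / report.aligned_bases)
        assert abs(report.mismatch_rate - 0.01) <= 3 * se

    def test_stratum_bases_sum_to_total(self):
        rng = np.random.default_rng(7)
        ref = "".join(np.array(list("ACGT"))[rng.choice(4, 5000)]) + "A" * 20
        spec = compose_sample([("r", ref, 1.0)])
        rs = simulate_short_reads(spec, 200, seed=4)
        report = error_rate_report(rs.placements, {"r": ref})
        assert report.stratum["bases"].sum() == report.aligned_bases


class TestRichards:
    @staticmethod
    def curve(x, A, D, B, C, E):
        return A + (D - A) / (1 + np.exp(-B * (x - C))) ** E

    def test_recovers_noise_free_parameters(self):
        x = np.linspace(-4, 6, 40)
        y = self.curve(x, 0.05, 0.95, 1.4, 1.0, 0.8)
        fit = fit_richards(x, y, seed=0)
        assert fit.rss < 1e-6
        assert np.allclose(fit.predict(x), y, atol=1e-3)

    def test_flat_data(self):
        x = np.linspace(0, 5, 10)
        y = np.full(10, 0.4)
        fit = fit_richards(x, y, seed=0)
        assert fit.rss == pytest.approx(0.0, abs=1e-8)
        assert fit.predict(np.array([100.0]))[0] == pytest.approx(0.4, abs=1e-3)

    def test_asymptotes_bounded(self):
        x = np.linspace(-3, 3, 20)
        y = self.curve(x, 0.1, 0.9, 2.0, 0.0, 1.0)
        fit = fit_richards(x, y, seed=1)
        lo, hi = sorted([fit.A, fit.D])
        pred = fit.predict(np.array([-1e6, 1e6]))
        assert np.all(pred >= lo - 1e-9) and np.all(pred <= hi + 1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="6 points"):
            fit_richards([0, 1, 2], [0.1, 0.5, 0.9])


class TestN50:
    @pytest.mark.parametrize(
        "lengths,expected",
        [([100], 100), ([2, 2, 2, 3, 3, 4, 8], 4), ([1, 1, 1, 1], 1)],
    )
    def test_examples(self, lengths, expected):
        assert n50(lengths) == expected

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        lengths = list(rng.integers(1, 1000, 50))
        shuffled = list(lengths)
        rng.shuffle(shuffled)
        assert n50(lengths) == n50(shuffled)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            n50([])
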