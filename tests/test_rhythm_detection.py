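from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dielshift import rhythm_detection as rd
from dielshift import synthetic_data as sd
from dielshift.core_io import ExpressionMatrix, SampleKey

from conftest import kendall_null_enumeration, kendall_s, permutation_pvalue

GRID = np.arange(0, 24, 2.0)


def _matrix_from_rows(rows, keys):
    df = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                      columns=[k.label for k in keys])
    return ExpressionMatrix(df, keys)


class TestFilterGenes:
    KEYS = [SampleKey(c, zt, 1) for c in ("WW", "DR") for zt in range(0, 24, 2)]

    def test_all_zero_gene_removed(self):
        m = _matrix_from_rows([[0.0] * 24, [1.0] * 24], self.KEYS)
        kept, removed = rd.filter_genes(m)
        assert removed == ["g0"] and kept.gene_ids == ["g1"]

    def test_total_below_five_removed(self):
        row = [4.9 / 24] * 24  # no zeros, total 4.9
        m = _matrix_from_rows([row, [1.0] * 24], self.KEYS)
        kept, removed = rd.filter_genes(m)
        assert removed == ["g0"]

    def test_boundary_total_exactly_five_kept(self):
        row = [5.0 / 24] * 24
        m = _matrix_from_rows([row], self.KEYS)
        kept, removed = rd.filter_genes(m)
        assert kept.gene_ids == ["g0"] and removed == []

    def test_toy_partition_of_ten(self):
        # 3 genes fail the total-TPM rule only, 3 fail the zero-fraction rule
        # only, one of each group is the same gene (fails both) -> 5 removed.
        rows = []
        # pass both rules
        for _ in range(5):
            rows.append([1.0] * 24)
        # fail total only (low but nonzero everywhere)
        for _ in range(2):
            rows.append([0.1] * 24)
        # fail zero-fraction only (6/24 zeros = 25%, high total)
        for _ in range(2):
            rows.append([0.0] * 6 + [10.0] * 18)
        # fail both
        rows.append([0.0] * 23 + [0.5])
        m = _matrix_from_rows(rows, self.KEYS)
        kept, removed = rd.filter_genes(m)
        assert len(kept.gene_ids) == 5 and len(removed) == 5

    def test_empty_matrix_rejected(self):
        df = pd.DataFrame(np.empty((0, len(self.KEYS))), columns=[k.label for k in self.KEYS])
        with pytest.raises(ValueError, match="empty"):
            rd.filter_genes(ExpressionMatrix(df, self.KEYS))


class TestExactNull:
    @pytest.mark.parametrize(
        "template",
        [
            [1, 2, 3, 4, 5],          # no ties
            [1, 1, 2, 2, 3, 3],       # pairs
            [1, 2, 2, 2, 3, 4],       # one triple
            [1, 1, 1, 2, 2, 2],       # two triples
        ],
    )
    def test_dp_matches_enumeration(self, template):
        ties = tuple(sorted(Counter(template).values()))
        m, counts = rd.kendall_null_counts(ties)
        enum = kendall_null_enumeration(template)
        # compare distributions of S = 2C - M
        total_dp = sum(counts)
        total_enum = sum(enum.values())
        for c in range(m + 1):
            s = 2 * c - m
            assert counts[c] / total_dp == pytest.approx(
                enum.get(s, 0) / total_enum, abs=0, rel=1e-15
            )

    def test_pvalue_matches_permutation_oracle_n5(self):
        # strictly monotone reference, 5 distinct values
        template = [0, 1, 2, 3, 4]
        x = [3, 0, 4, 1, 2]
        p_dp = rd.kendall_s_pvalue(kendall_s(x, template), (1, 1, 1, 1, 1))
        assert p_dp == pytest.approx(permutation_pvalue(x, template), abs=1e-15)

    def test_pvalue_with_template_ties(self):
        template = [1, 1, 2, 2, 3]
        x = [5, 2, 4, 1, 3]
        ties = tuple(sorted(Counter(template).values()))
        p_dp = rd.kendall_s_pvalue(kendall_s(x, template), ties)
        assert p_dp == pytest.approx(permutation_pvalue(x, template), abs=1e-15)

    def test_null_counts_sum_to_multinomial(self):
        m, counts = rd.kendall_null_counts((2, 2, 2))
        assert sum(counts) == 720 // 8  # 6! / (2!2!2!)
        assert m == (36 - 12) // 2


class TestJtkScan:
    def test_constant_series(self):
        r = rd.jtk_scan([5.0] * 12, GRID)
        assert r.p_value == 1.0 and r.tau == 0.0

    def test_noiseless_cosine_phase_and_pointmass(self):
        x = 10 + 3 * np.cos(2 * np.pi * (GRID - 4) / 24)
        r = rd.jtk_scan(x, GRID, per_gene_bonferroni=False)
        assert r.phase == 4.0 and r.tau == 1.0
        # exact point mass of |S| = S_max: 2 orderings of the
        # 12!/(2!^5) distinguishable arrangements
        import math

        expected = 2 * (2**5) / math.factorial(12)
        assert r.p_value == pytest.approx(expected, rel=1e-12)

    def test_bonferroni_factor_counts_distinct_templates(self):
        x = 10 + 3 * np.cos(2 * np.pi * (GRID - 4) / 24)
        raw = rd.jtk_scan(x, GRID, per_gene_bonferroni=False)
        adj = rd.jtk_scan(x, GRID, per_gene_bonferroni=True)
        assert adj.n_templates == 12
        assert adj.p_value == pytest.approx(min(1.0, raw.p_value * 12))

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError, match="4 distinct timepoints"):
            rd.jtk_scan([1, 2, 3], [0.0, 8.0, 16.0])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            rd.jtk_scan([1.0, np.nan] + [1.0] * 10, GRID)

    def test_phase_equivariance(self):
        rng = np.random.default_rng(8)
        x = 10 + 5 * np.cos(2 * np.pi * (GRID - 6) / 24) + rng.normal(0, 0.5, 12)
        base = rd.jtk_scan(x, GRID)
        for delta in (2, 4, 10):
            shifted = np.roll(x, delta // 2)  # grid step is 2 h
            r = rd.jtk_scan(shifted, GRID)
            assert r.phase == (base.phase + delta) % 24

    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(3)
        x = 10 + 4 * np.cos(2 * np.pi * (GRID - 8) / 24) + rng.normal(0, 1, 12)
        a = rd.jtk_scan(x, GRID)
        b = rd.jtk_scan(x * scale, GRID)
        assert b.p_value == a.p_value and b.phase == a.phase and b.tau == a.tau

    def test_monotone_power_in_amplitude(self):
        times = np.repeat(GRID, 3)
        rng = np.random.default_rng(11)
        noise = rng.normal(0, 2.0, size=(300, len(times)))
        rates = []
        for amp in (1.0, 3.0, 6.0):
            x = 10 + amp * np.cos(2 * np.pi * (times - 4) / 24) + noise
            calls = rd.call_cycling(rd.scan_matrix(x, times), alpha=0.05)
            rates.append(calls["cycling"].mean())
        assert rates[0] <= rates[1] <= rates[2]


class TestCallCycling:
    def test_boundary_not_cycling(self):
        n = 100
        calls = pd.DataFrame({"p_value": [0.05 / n] + [1.0] * (n - 1)})
        out = rd.call_cycling(calls, alpha=0.05)
        assert out["adj_p"].iloc[0] == pytest.approx(0.05)
        assert not out["cycling"].iloc[0]

    def test_single_gene_identity(self):
        out = rd.call_cycling(pd.DataFrame({"p_value": [0.03]}), alpha=0.05)
        assert out["adj_p"].iloc[0] == 0.03 and bool(out["cycling"].iloc[0])

    def test_adj_p_at_least_p(self):
        calls = pd.DataFrame({"p_value": np.linspace(0, 1, 17)})
        out = rd.call_cycling(calls)
        assert (out["adj_p"] >= out["p_value"]).all()


class TestPhaseAmplitude:
    def test_noiseless_closed_form(self):
        t = GRID
        x = 10 + 3 * np.cos(2 * np.pi * (t - 6) / 24)
        phase, amp = rd.estimate_phase_amplitude(x, t, 24, 6)
        assert phase == 6 and amp == pytest.approx(3.0, abs=1e-12)

    def test_flat_series_zero_amplitude(self):
        _, amp = rd.estimate_phase_amplitude([7.0] * 12, GRID, 24, 0)
        assert amp == 0.0

    def test_unbiased_under_noise(self):
        t = GRID
        amps = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = 10 + 5 * np.cos(2 * np.pi * (t - 4) / 24) + rng.normal(0, 1, len(t))
            _, amp = rd.estimate_phase_amplitude(x, t, 24, 4)
            amps.append(amp)
        assert abs(np.mean(amps) - 5.0) < 0.5


class TestDetectRhythms:
    def test_signal_recovery_noiseless(self):
        truths = [
            sd.GeneTruth("cyc_ww", "WW_only", amplitude_ww=5, phase_ww=6),
            sd.GeneTruth("cyc_both", "both", amplitude_ww=5, amplitude_dr=5,
                         phase_ww=2, phase_dr=10),
            sd.GeneTruth("flat", "arrhythmic", baseline_ww=8, baseline_dr=8),
        ]
        m = sd.generate_expression(sd.DielDesign(), truths, seed=0)
        ww = rd.detect_rhythms(m, "WW")
        dr = rd.detect_rhythms(m, "DR")
        assert bool(ww.loc["cyc_ww", "cycling"]) and bool(ww.loc["cyc_both", "cycling"])
        assert not bool(ww.loc["flat", "cycling"])
        assert not bool(dr.loc["cyc_ww", "cycling"]) and bool(dr.loc["cyc_both", "cycling"])
        assert ww.loc["cyc_both", "phase"] == 2 and dr.loc["cyc_both", "phase"] == 10

    def test_missing_replicates_supported(self):
        truths = [sd.GeneTruth("g", "both", amplitude_ww=5, amplitude_dr=5,
                               phase_ww=4, phase_dr=4)]
        m = sd.generate_expression(sd.study_design(), truths, seed=0)
        ww = rd.detect_rhythms(m, "WW")
        dr = rd.detect_rhythms(m, "DR")
        assert bool(ww.loc["g", "cycling"]) and bool(dr.loc["g", "cycling"])

    def test_collapse_replicates_option(self):
        truths = [sd.GeneTruth("g", "both", amplitude_ww=5, amplitude_dr=5,
                               phase_ww=4, phase_dr=4, noise_sd=0.5)]
        m = sd.generate_expression(sd.DielDesign(), truths, seed=1)
        out = rd.detect_rhythms(m, "WW", collapse_replicates=True)
        assert bool(out.loc["g", "cycling"]) and out.loc["g", "phase"] == 4
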