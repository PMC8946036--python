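import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from circlact import synth
from circlact.diffexpr import (
    DEThresholds,
    base_means,
    estimate_dispersion,
    nb_exact_test,
    run_de,
    size_factors,
)

GROUPS6 = {
    **{f"non_lactation_{j}": "non_lactation" for j in range(3)},
    **{f"early_lactation_{j}": "early_lactation" for j in range(3)},
}
COLS6 = list(GROUPS6)


def nb_exact_brute(kA, kB, sA, sB, disp_a, disp_b=None):
    """Independent O(K) enumeration with scipy pmfs in linear space."""
    disp_b = disp_a if disp_b is None else disp_b
    K = kA + kB
    if K == 0:
        return 1.0
    q = K / (sA + sB)

    def pmf(k, mean, disp):
        if disp <= 1e-8:
            return stats.poisson.pmf(k, mean)
        size = 1.0 / disp
        return stats.nbinom.pmf(k, size, size / (size + mean))

    probs = [pmf(a, q * sA, disp_a) * pmf(K - a, q * sB, disp_b) for a in range(K + 1)]
    obs = probs[kA]
    return sum(p for p in probs if p <= obs * (1 + 1e-10)) / sum(probs)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        c = pd.DataFrame({"a": [5, 10, 20], "b": [5, 10, 20]})
        assert np.allclose(size_factors(c), 1.0)

    def test_doubled_sample_splits_symmetrically(self):
        c = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        f = size_factors(c)
        assert f["a"] == pytest.approx(1 / math.sqrt(2), abs=1e-6)
        assert f["b"] == pytest.approx(math.sqrt(2), abs=1e-6)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(0)
        c = pd.DataFrame(rng.integers(1, 500, size=(40, 4)))
        perm = c.sample(frac=1, random_state=1)
        assert np.allclose(size_factors(c), size_factors(perm))

    def test_zero_heavy_matrix_falls_back(self):
        c = pd.DataFrame({"a": [0, 10, 4], "b": [5, 0, 4], "c": [5, 10, 0]})
        f = size_factors(c)
        assert (f > 0).all()


class TestNbExactTest:
    def test_symmetric_observation_has_p_one(self):
        assert nb_exact_test(17, 17, 1.0, 1.0, 0.1) == pytest.approx(1.0)

    def test_poisson_limit_binomial_value(self):
        # equal size factors, all mass on a=0..10, Binomial(10, 1/2):
        # only the two extreme outcomes are as unlikely as (0,10)
        assert nb_exact_test(0, 10, 1.0, 1.0, 0.0) == pytest.approx(2 / 1024)

    def test_empty_total_is_uninformative(self):
        assert nb_exact_test(0, 0, 1.0, 1.0, 0.1) == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            nb_exact_test(-1, 5, 1, 1, 0.1)
        with pytest.raises(ValueError):
            nb_exact_test(1, 5, 1, 1, -0.1)
        with pytest.raises(ValueError):
            nb_exact_test(1, 5, 0, 1, 0.1)

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(
        kA=st.integers(0, 100),
        kB=st.integers(0, 100),
        sA=st.floats(0.3, 4.0),
        sB=st.floats(0.3, 4.0),
        disp=st.sampled_from([0.0, 0.01, 0.1, 0.5]),
    )
    def test_matches_brute_force_enumeration(self, kA, kB, sA, sB, disp):
        assert nb_exact_test(kA, kB, sA, sB, disp) == pytest.approx(
            nb_exact_brute(kA, kB, sA, sB, disp), rel=1e-9
        )


class TestDispersion:
    def _sim(self, seed, alpha, n_rows=300, n_per_group=3, mu=100.0):
        rng = np.random.default_rng(seed)
        cols = {}
        samples = [f"non_lactation_{j}" for j in range(n_per_group)] + [
            f"early_lactation_{j}" for j in range(n_per_group)
        ]
        for s in samples:
            cols[s] = synth.nb_draw(rng, np.full(n_rows, mu), alpha)
        counts = pd.DataFrame(cols)
        groups = {s: ("non_lactation" if "non" in s else "early_lactation")
                  for s in samples}
        return counts, groups

    def test_underdispersed_rows_have_zero_raw_estimate(self):
        counts = pd.DataFrame({c: [50, 7] for c in COLS6})  # constant rows
        raw = estimate_dispersion(counts, GROUPS6, shrink_weight=0.0)
        assert (raw == 0).all()

    def test_recovers_generating_dispersion_at_n20(self):
        counts, groups = self._sim(7, alpha=0.1, n_per_group=20)
        est = estimate_dispersion(counts, groups)
        assert 0.05 <= est.median() <= 0.2

    def test_single_sample_groups_fall_back_to_trend(self):
        counts = pd.DataFrame({"non_lactation_0": [10, 50],
                               "early_lactation_0": [12, 48]})
        groups = {"non_lactation_0": "non_lactation",
                  "early_lactation_0": "early_lactation"}
        est = estimate_dispersion(counts, groups)
        assert est.notna().all()


class TestRunDe:
    def _matrix(self, seed, n=200, de_idx=(), lfc=0.0, mu=200.0, alpha=0.1):
        rng = np.random.default_rng(seed)
        sf = 2.0 ** rng.uniform(-0.5, 0.5, 6)
        data = {}
        for j, s in enumerate(COLS6):
            m = np.full(n, mu)
            if GROUPS6[s] == "early_lactation" and len(de_idx):
                m = m.copy()
                m[list(de_idx)] *= 2.0**lfc
            data[s] = synth.nb_draw(rng, m * sf[j], alpha)
        return pd.DataFrame(data, index=[f"c{i:04d}" for i in range(n)])

    def test_planted_upregulation_direction(self):
        counts = self._matrix(3, de_idx=range(20), lfc=3.0)
        res = run_de(counts, GROUPS6).set_index("circ_id")
        planted = [f"c{i:04d}" for i in range(20)]
        assert (res.loc[planted, "direction"] == "up").all()
        assert res.loc[planted, "significant"].mean() > 0.9

    def test_scale_invariance_of_fold_change(self):
        counts = self._matrix(4, de_idx=range(10), lfc=2.0)
        res1 = run_de(counts, GROUPS6).set_index("circ_id")
        res2 = run_de(counts * 2, GROUPS6).set_index("circ_id")
        assert np.allclose(
            res1["log2_fold_change"],
            res2.loc[res1.index, "log2_fold_change"],
            equal_nan=True,
        )

    def test_zero_rows_reported_not_dropped(self):
        counts = self._matrix(5, n=10)
        counts.iloc[3] = 0
        res = run_de(counts, GROUPS6).set_index("circ_id")
        row = res.loc[counts.index[3]]
        assert row["p_value"] == 1.0
        assert np.isnan(row["log2_fold_change"])
        assert not row["significant"]

    def test_bh_monotone_in_rank(self):
        counts = self._matrix(6, de_idx=range(30), lfc=2.0)
        res = run_de(counts, GROUPS6)
        by_raw = res.sort_values("p_value")
        assert (np.diff(by_raw["adjusted_p"]) >= -1e-12).all()
        assert (res["adjusted_p"] >= res["p_value"] - 1e-12).all()

    def test_base_mean_is_normalized_mean(self):
        counts = self._matrix(8, n=20)
        f = size_factors(counts)
        expected = (counts / f).mean(axis=1)
        res = run_de(counts, GROUPS6).set_index("circ_id")
        assert np.allclose(res["base_mean"], expected[res.index])

    def test_requires_both_groups(self):
        counts = self._matrix(9, n=5)
        groups = {s: "non_lactation" for s in COLS6}
        with pytest.raises(ValueError):
            run_de(counts, groups)
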