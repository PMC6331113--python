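"""Closed-form oracle tests: analytic family expressions vs the general
implementation, plus the extrema, crossings and limits that characterize
the binary pathology of CEN."""

import math

import numpy as np
import pytest

import mcen.closed_forms as cf
import mcen.families as fam
from mcen.core_metrics import score

GRID = np.logspace(-3, 3, 220)
MEASURES = ("cen", "mcen", "acc_star", "mcc_star")


def _assert_oracle(matrix, closed, tol=1e-9):
    rep = score(matrix)
    for m in MEASURES:
        assert getattr(rep, m) == pytest.approx(closed[m], abs=tol), m


class TestOracleEquivalence:
    """The central check: closed forms == general implementation on dense grids."""

    @pytest.mark.parametrize("n", [2, 3, 4, 6])
    def test_symbal(self, n):
        for g in np.linspace(0.0, 20.0, 220):
            _assert_oracle(fam.make_symbal(n, g, 1.0), cf.symbal(n, g))

    def test_binary_general(self, rng):
        for _ in range(220):
            tp, fn, fp, tn = rng.gamma(0.8, 10.0, size=4)
            _assert_oracle(
                [[tp, fn], [fp, tn]], cf.binary_general(tp, fn, fp, tn)
            )

    def test_u_family(self):
        for a in GRID:
            _assert_oracle(fam.make_u(a), cf.u_family(a))

    def test_v_family(self):
        for a in GRID:
            _assert_oracle(fam.make_v(a), cf.v_family(a))

    @pytest.mark.parametrize("r", [0.1, 0.5, 0.8, 1.0, 2.0, 5.0])
    def test_x_family(self, r):
        for a in np.logspace(-2, 2, 40):
            _assert_oracle(fam.make_x(a, r), cf.x_family(a, r))

    @pytest.mark.parametrize("r", [0.1, 0.5, 0.71, 1.0, 1.4, 5.0])
    def test_y_family(self, r):
        for a in np.logspace(-2, 2, 40):
            _assert_oracle(fam.make_y(a, r), cf.y_family(a, r))

    @pytest.mark.parametrize("n", [2, 3, 4, 6])
    def test_z_family(self, n):
        for a in np.logspace(-2, 2, 60):
            _assert_oracle(fam.make_z(n, a), cf.z_family(n, a))

    def test_family_measures_dispatch(self):
        p = cf.FamilyParams(family="z", n_classes=4, A=10.0)
        assert cf.family_measures(p) == cf.z_family(4, 10.0)


class TestSymmetricBalanced:
    def test_complete_misclassification_scores_one(self):
        for n in (2, 3, 5):
            v = cf.symbal(n, 0.0)
            assert v["cen"] == pytest.approx(1.0)
            assert v["mcen"] == pytest.approx(1.0)
            assert v["acc_star"] == pytest.approx(1.0)

    def test_binary_gamma_five(self):
        v = cf.symbal(2, 5.0)
        assert round(v["cen"], 4) == 0.5975
        assert round(v["mcen"], 4) == 0.5910

    def test_duality_mcen_double_gamma_is_cen(self):
        # For N > 2 the MCEN curve is the CEN curve traversed at half speed
        for n in range(3, 7):
            for g in np.linspace(0.0, 12.0, 60):
                assert cf.symbal(n, 2 * g)["mcen"] == pytest.approx(
                    cf.symbal(n, g)["cen"], abs=1e-12
                )

    def test_measure_ordering_multiclass(self):
        # N > 2, gamma > 0: MCC* < ACC* < CEN < MCEN
        for n in (3, 4, 6):
            for g in np.linspace(0.05, 15.0, 50):
                v = cf.symbal(n, g)
                assert v["mcc_star"] < v["acc_star"] < v["cen"] < v["mcen"]

    def test_rejects_negative_gamma(self):
        with pytest.raises(ValueError):
            cf.symbal(2, -0.5)


class TestExtremaAndCrossings:
    def test_binary_cen_maximum_at_e_half_minus_one(self):
        res = cf.find_extremum("cen", "symbal", (0.0, 2.0), n_classes=2)
        assert res.location == pytest.approx(math.e / 2 - 1, abs=1e-6)
        assert res.value == pytest.approx(1.06148, abs=5e-6)

    def test_u_family_cen_maximum(self):
        res = cf.find_extremum("cen", "u", (0.5, 10.0))
        assert res.location == pytest.approx(2.54, abs=5e-3)
        assert res.value > 1.0

    def test_z_binary_unit_crossings(self):
        roots = cf.find_unit_crossings("cen", "z", (0.5, 3.0), n_classes=2)
        locs = [r.location for r in roots]
        assert len(locs) == 2
        assert locs[0] == pytest.approx(1.0, abs=1e-8)
        assert locs[1] == pytest.approx(1.85, abs=5e-3)

    def test_v_family_unit_crossings(self):
        locs = [r.location for r in cf.find_unit_crossings("cen", "v", (0.5, 3.0))]
        assert len(locs) == 2
        assert locs[0] == pytest.approx(1.0, abs=1e-8)
        assert locs[1] == pytest.approx(1.41, abs=5e-2)

    def test_cen_mcen_crossing_points(self):
        # gamma_0 ~ 5.78 for the binary symmetric case; A_0 ~ 0.24 for U
        g0 = cf.find_crossing("cen", "mcen", "symbal", (1.0, 10.0), n_classes=2)
        assert g0.location == pytest.approx(5.78, abs=5e-2)
        a0 = cf.find_crossing("cen", "mcen", "u", (0.05, 0.8))
        assert a0.location == pytest.approx(0.24, abs=5e-2)

    def test_no_root_raises(self):
        with pytest.raises(cf.NoRootError):
            cf.find_unit_crossings("acc_star", "u", (0.1, 0.5))


class TestLimits:
    def test_u_family_limits(self):
        for m in MEASURES:
            assert cf.limit_at_infinity(m, cf.FamilyParams("u")) == 1.0
            # numeric corroboration at large A
            assert cf.u_family(1e8)[m] == pytest.approx(1.0, abs=1e-6)

    def test_v_family_limits(self):
        p = cf.FamilyParams("v")
        assert cf.limit_at_infinity("cen", p) == 0.0
        assert cf.limit_at_infinity("mcc_star", p) == pytest.approx(
            (2 + math.sqrt(2)) / 4
        )

    @pytest.mark.parametrize("r", [0.13, 0.5, 1.0, 2.0, 10.0])
    def test_x_limit_formulas_match_numeric(self, r):
        lim = cf.x_limits(r)
        at_large = cf.x_family(1e9, r)
        for m in MEASURES:
            assert lim[m] == pytest.approx(at_large[m], abs=1e-6)

    @pytest.mark.parametrize("r", [0.5, 0.71, 1.0, 1.4, 5.0])
    def test_y_limit_formulas_match_numeric(self, r):
        lim = cf.y_limits(r)
        at_large = cf.y_family(1e9, r)
        for m in MEASURES:
            assert lim[m] == pytest.approx(at_large[m], abs=1e-6)

    def test_x_limit_unit_threshold(self):
        # l_CEN(r) reaches 1 exactly at r = 1; it stays below 1 on (r_0, 1)
        # even though the interior maximum over A already exceeds 1 there
        assert cf.x_limits(1.0)["cen"] == pytest.approx(1.0)
        assert cf.x_limits(1.2)["cen"] > 1.0
        assert cf.x_limits(0.9)["cen"] < 1.0

    def test_x_threshold_r0_where_cen_first_leaves_range(self):
        # r_0 ~ 0.8 solves max_A CEN(A; r) = 1
        from scipy.optimize import brentq

        def peak(r):
            return cf.find_extremum("cen", "x", (0.1, 1e4), r=r).value

        r0 = brentq(lambda r: peak(r) - 1.0, 0.5, 0.99, xtol=1e-6)
        assert r0 == pytest.approx(0.8, abs=5e-2)
        assert peak(r0 + 0.05) > 1.0
        assert peak(r0 - 0.05) < 1.0

    def test_x_limit_ordering_thresholds(self):
        from scipy.optimize import brentq

        # r_1: l_MCEN = l_CEN; r_2: l_CEN = l_MCC*; r_3: l_MCC* = l_MCEN
        r1 = brentq(
            lambda r: cf.x_limits(r)["mcen"] - cf.x_limits(r)["cen"], 0.16, 0.5
        )
        r2 = brentq(
            lambda r: cf.x_limits(r)["cen"] - cf.x_limits(r)["mcc_star"], 0.14, 0.2
        )
        r3 = brentq(
            lambda r: cf.x_limits(r)["mcc_star"] - cf.x_limits(r)["mcen"], 0.05, 0.14
        )
        assert 0 < r3 < r2 < r1 < 0.8
        assert r1 == pytest.approx(0.23, abs=5e-3)
        assert r2 == pytest.approx(0.15, abs=5e-3)
        assert r3 == pytest.approx(0.13, abs=5e-3)

    def test_y_limit_unit_threshold(self):
        from scipy.optimize import brentq

        # L_CEN(r) = 1 at R_0 ~ 0.71 and at r = 1
        assert cf.y_limits(1.0)["cen"] == pytest.approx(1.0)
        r0 = brentq(lambda r: cf.y_limits(r)["cen"] - 1.0, 0.3, 0.9)
        assert r0 == pytest.approx(0.71, abs=5e-3)

    def test_y_acc_mcc_limit_order_threshold(self):
        # L_ACC* < L_MCC* iff r > (sqrt(5)-1)/4
        r_star = (math.sqrt(5) - 1) / 4
        lo, hi = cf.y_limits(r_star - 0.01), cf.y_limits(r_star + 0.01)
        assert lo["acc_star"] > lo["mcc_star"]
        assert hi["acc_star"] < hi["mcc_star"]

    def test_z_family_limits(self):
        for n in (2, 3):
            p = cf.FamilyParams("z", n_classes=n)
            assert cf.limit_at_infinity("cen", p) == 0.0
            expected_mcc = 0.75 if n == 2 else 5 / 8
            assert cf.limit_at_infinity("mcc_star", p) == pytest.approx(expected_mcc)
            assert cf.z_family(n, 1e8)["mcc_star"] == pytest.approx(
                expected_mcc, abs=1e-6
            )


class TestMonotonicityClaims:
    def test_u_family_monotone_except_cen(self):
        grid = np.logspace(-2, 2, 200)
        vals = {m: np.array([cf.u_family(a)[m] for a in grid]) for m in MEASURES}
        for m in ("mcen", "acc_star", "mcc_star"):
            assert np.all(np.diff(vals[m]) > 0), m
        assert np.any(np.diff(vals["cen"]) < 0)  # interior maximum
        assert np.all(vals["mcen"] < 1.0)
        assert np.all(vals["acc_star"] < vals["mcc_star"])

    @pytest.mark.parametrize("r", [0.5, 1.0, 2.0])
    def test_x_family_monotone_measures(self, r):
        grid = np.logspace(-2, 3, 200)
        vals = {m: np.array([cf.x_family(a, r)[m] for a in grid]) for m in MEASURES}
        for m in ("acc_star", "mcc_star"):
            assert np.all(np.diff(vals[m]) > 0), m
        assert np.all(vals["mcen"] < 1.0)

    def test_x_family_mcen_increasing_larger_r(self):
        grid = np.logspace(-2, 3, 200)
        mc = np.array([cf.x_family(a, 2.0)["mcen"] for a in grid])
        assert np.all(np.diff(mc) > 0)

    @pytest.mark.parametrize("r", [0.5, 1.0])
    def test_x_family_mcen_overshoots_limit_at_small_r(self, r):
        # for r <= 1 the MCEN profile rises above its A -> inf limit and
        # then decreases toward it, so it is not globally increasing in A
        lim = cf.x_limits(r)["mcen"]
        grid = np.logspace(0, 5, 300)
        mc = np.array([cf.x_family(a, r)["mcen"] for a in grid])
        assert mc.max() > lim
        assert np.any(np.diff(mc) < 0)
        assert mc[-1] == pytest.approx(lim, abs=1e-3)

    def test_x_family_cen_interior_maximum_above_unit_threshold(self):
        # for r > r_0 the CEN profile over A peaks above 1, then falls
        # back toward its limit l_CEN(r)
        grid = np.logspace(-2, 5, 300)
        cen = np.array([cf.x_family(a, 2.0)["cen"] for a in grid])
        k = int(np.argmax(cen))
        assert 0 < k < len(cen) - 1
        assert cen[k] > 1.0
        assert cen[k] > cf.x_limits(2.0)["cen"]

    def test_v_family_out_of_range_window(self):
        # CEN > 1 exactly on (1, A_1) with A_1 ~ 1.41
        assert cf.v_family(1.0)["cen"] == pytest.approx(1.0)
        assert cf.v_family(1.2)["cen"] > 1.0
        assert cf.v_family(1.5)["cen"] < 1.0
        assert cf.v_family(0.5)["cen"] < 1.0
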