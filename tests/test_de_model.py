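import math

import numpy as np
import pytest

from fuzzydea.de_model import (
    DEModelError,
    DEThresholdModel,
    de_possibilities,
    fit_hyperbolas,
    joint_relation,
    membership_surfaces,
)
from fuzzydea.fuzzy_counts import TrapezoidalCount


def flat_model(t: float = 0.5, m_lo: float = 0.1, m_hi: float = 1e6) -> DEThresholdModel:
    """A model with an (almost) constant envelope t(m) = t, for exact checks."""
    return DEThresholdModel(
        a=1e-12, b=t, c=0.0, q=0.99, m_lo=m_lo, m_hi=m_hi,
        bin_centers=np.array([m_lo, m_hi]), bin_thresholds=np.array([t, t]),
    )


def random_trapezoid(rng, hi=300.0) -> TrapezoidalCount:
    return TrapezoidalCount(*sorted(rng.uniform(0.0, hi, 4)))


class TestFitHyperbolas:
    def test_recovers_known_envelope(self):
        """Points spread along a |fc| = 4/m boundary; the fitted threshold
        tracks it within 5% across two decades."""
        rng = np.random.default_rng(42)
        m = np.exp(rng.uniform(np.log(0.5), np.log(128.0), 30000))
        fc = (4.0 / m) * rng.choice([-1.0, 1.0], m.size)
        model = fit_hyperbolas(
            np.column_stack([m, fc]), q=0.99, min_m=0.5, n_bins=80
        )
        assert model.method == "hyperbola"
        for mm in (1.0, 10.0, 100.0):
            assert model.threshold(mm) == pytest.approx(4.0 / mm, rel=0.05)

    def test_threshold_strictly_decreasing_and_positive(self, null_model):
        ms = np.geomspace(null_model.m_lo, null_model.m_hi, 50)
        ts = np.asarray(null_model.threshold(ms))
        assert np.all(ts > 0)
        assert np.all(np.diff(ts) < 0)

    def test_quantile_envelope_contains_q_fraction(self, null_model):
        rng = np.random.default_rng(7)
        m = np.exp(rng.uniform(np.log(1.5), np.log(2000.0), 4000))
        fc = rng.normal(0.0, 0.25, m.size)
        inside = np.abs(fc) <= np.asarray(null_model.threshold(m))
        assert inside.mean() >= 0.95  # q=0.99 per log-spaced bin

    def test_identical_samples_collapse_envelope(self):
        rng = np.random.default_rng(3)
        m = np.exp(rng.uniform(np.log(2), np.log(500), 500))
        pts = np.column_stack([m, np.zeros_like(m)])
        model = fit_hyperbolas(pts)
        ts = np.asarray(model.threshold(np.geomspace(2, 500, 20)))
        assert np.all(ts <= 2 * model.t_floor + 1e-9)
        # with a collapsed envelope, identical counts are fully same-expressed
        de = de_possibilities(
            TrapezoidalCount(50, 50, 50, 50), TrapezoidalCount(50, 50, 50, 50), model
        )
        assert de.same == pytest.approx(1.0)

    def test_too_few_points_errors(self):
        with pytest.raises(DEModelError, match="at least"):
            fit_hyperbolas(np.array([[10.0, 0.5]] * 10))

    def test_infinite_fc_points_excluded(self):
        rng = np.random.default_rng(11)
        m = np.exp(rng.uniform(np.log(2), np.log(500), 300))
        fc = rng.normal(0, 0.2, m.size)
        pts = np.column_stack([m, fc])
        pts[::50, 1] = np.inf
        model = fit_hyperbolas(pts)
        assert np.isfinite(model.threshold(10.0))

    def test_round_trip_dict(self, null_model):
        again = DEThresholdModel.from_dict(null_model.to_dict())
        assert again.threshold(25.0) == pytest.approx(null_model.threshold(25.0))


class TestMembershipSurfaces:
    def test_half_crossings_at_threshold(self, null_model):
        for m in (5.0, 50.0, 500.0):
            s = membership_surfaces(null_model, m)
            assert s.same(0.0) == pytest.approx(1.0)
            assert s.same(s.t) == pytest.approx(0.5)
            assert s.same(-s.t) == pytest.approx(0.5)
            assert s.over(s.t) == pytest.approx(0.5)
            assert s.under(-s.t) == pytest.approx(0.5)

    def test_sigmoid_tails(self, null_model):
        s = membership_surfaces(null_model, 20.0)
        assert s.over(3 * s.t) > 0.99
        assert s.over(0.0) == pytest.approx(0.01, abs=1e-9)
        assert s.under(0.0) == pytest.approx(0.01, abs=1e-9)
        assert s.over(math.inf) == 1.0
        assert s.same(math.inf) == 0.0

    def test_wider_at_low_expression(self, null_model):
        lo = membership_surfaces(null_model, 5.0)
        hi = membership_surfaces(null_model, 500.0)
        assert lo.t > hi.t
        assert lo.same(0.3) > hi.same(0.3)

    def test_invalid_mean_rejected(self, null_model):
        with pytest.raises(DEModelError):
            membership_surfaces(null_model, 0.0)
        with pytest.raises(DEModelError):
            membership_surfaces(null_model, -3.0)


class TestJointRelation:
    def test_core_product_is_one(self):
        rel = joint_relation(TrapezoidalCount(2, 4, 6, 9), TrapezoidalCount(1, 3, 3, 5))
        assert rel(5.0, 3.0) == 1.0

    def test_outside_support_is_zero(self):
        rel = joint_relation(TrapezoidalCount(2, 4, 6, 9), TrapezoidalCount(1, 3, 3, 5))
        assert rel(1.0, 3.0) == 0.0
        assert rel(5.0, 6.0) == 0.0

    def test_shoulder_takes_min_with_core(self):
        case = TrapezoidalCount(2, 4, 6, 9)
        rel = joint_relation(case, TrapezoidalCount(1, 3, 3, 5))
        x = 2.0  # on the rising shoulder of the case trapezoid
        assert rel(x, 3.0) == pytest.approx(case.membership(x))


class TestDePossibilities:
    def test_identical_counts_fully_same(self, null_model):
        t = TrapezoidalCount(40, 45, 50, 60)
        de = de_possibilities(t, t, null_model)
        assert de.same == pytest.approx(1.0)

    def test_strong_change_of_certain_counts(self, null_model):
        de = de_possibilities(
            TrapezoidalCount(400, 400, 400, 400),
            TrapezoidalCount(50, 50, 50, 50),
            null_model,
        )
        assert de.over == pytest.approx(1.0, abs=1e-6)
        assert de.same == pytest.approx(0.0, abs=1e-6)
        assert de.under == pytest.approx(0.0, abs=1e-6)

    def test_point_counts_on_the_envelope_are_half_half(self):
        model = flat_model(t=0.5)
        n2 = 100.0
        n1 = n2 * 2 ** 0.5  # fc exactly at the 0.5 crossing
        de = de_possibilities(
            TrapezoidalCount(n1, n1, n1, n1), TrapezoidalCount(n2, n2, n2, n2), model
        )
        assert de.over == pytest.approx(0.5, abs=1e-9)
        assert de.same == pytest.approx(0.5, abs=1e-9)

    def test_point_counts_match_direct_surface_evaluation(self, null_model):
        """Crisp counts reduce the sup-min to a single surface lookup."""
        rng = np.random.default_rng(21)
        for _ in range(20):
            n1, n2 = rng.uniform(2.0, 800.0, 2)
            de = de_possibilities(
                TrapezoidalCount(n1, n1, n1, n1),
                TrapezoidalCount(n2, n2, n2, n2),
                null_model,
            )
            s = membership_surfaces(null_model, (n1 + n2) / 2.0)
            fc = math.log2(n1 / n2)
            assert de.over == pytest.approx(s.over(fc), abs=1e-9)
            assert de.same == pytest.approx(s.same(fc), abs=1e-9)
            assert de.under == pytest.approx(s.under(fc), abs=1e-9)

    def test_swap_symmetry(self, null_model):
        rng = np.random.default_rng(8)
        for _ in range(10):
            a, b = random_trapezoid(rng), random_trapezoid(rng)
            fwd = de_possibilities(a, b, null_model)
            rev = de_possibilities(b, a, null_model)
            # the local refinement search may break ties differently in the
            # two orientations; symmetry holds to grid tolerance
            assert fwd.over == pytest.approx(rev.under, abs=1e-4)
            assert fwd.under == pytest.approx(rev.over, abs=1e-4)
            assert fwd.same == pytest.approx(rev.same, abs=1e-4)

    def test_grid_refinement_converges(self, null_model):
        rng = np.random.default_rng(13)
        for _ in range(10):
            a, b = random_trapezoid(rng), random_trapezoid(rng)
            p64 = de_possibilities(a, b, null_model, grid_n=64)
            p128 = de_possibilities(a, b, null_model, grid_n=128)
            assert abs(p64.over - p128.over) < 0.01
            assert abs(p64.same - p128.same) < 0.01
            assert abs(p64.under - p128.under) < 0.01

    def test_widening_never_reduces_possibility(self, null_model):
        rng = np.random.default_rng(17)
        for _ in range(10):
            a, b = random_trapezoid(rng), random_trapezoid(rng)
            base = de_possibilities(a, b, null_model)
            wide = TrapezoidalCount(max(a.a - 10, 0.0), a.b, a.c, a.d + 10)
            out = de_possibilities(wide, b, null_model)
            # sup over a superset; tolerance covers grid re-sampling
            assert out.over >= base.over - 0.01
            assert out.same >= base.same - 0.01
            assert out.under >= base.under - 0.01

    def test_one_verdict_always_at_least_half(self, null_model):
        rng = np.random.default_rng(29)
        for _ in range(25):
            a, b = random_trapezoid(rng), random_trapezoid(rng)
            de = de_possibilities(a, b, null_model)
            assert de.max_possibility >= 0.5 - 1e-9

    def test_zero_vs_expressed_is_extreme(self, null_model):
        de = de_possibilities(
            TrapezoidalCount(0, 0, 0, 0), TrapezoidalCount(200, 200, 200, 200),
            null_model,
        )
        assert de.under == pytest.approx(1.0)
        assert de.same == pytest.approx(0.0, abs=1e-6)

    def test_both_zero_is_degenerate_same(self, null_model):
        de = de_possibilities(
            TrapezoidalCount.ZERO, TrapezoidalCount.ZERO, null_model
        )
        assert (de.under, de.same, de.over) == (0.0, 1.0, 0.0)
        assert de.degenerate
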