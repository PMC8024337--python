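import math

import numpy as np
import pytest
from scipy import stats

from cytosim.cytonemes import (_ReceiverIndex, cytoneme_step, decay_receivers,
                               deposit, deposition_fires, detect_contact,
                               replace_cytoneme, retraction_due,
                               sample_cytoneme_angle, sample_growth_increment,
                               tip_position)
from cytosim.errors import IntegrityError, ParameterError
from cytosim.params import Params
from cytosim.tissue_init import (Cell, RECEIVER, SOURCE, init_cytonemes,
                                 make_yolk, seed_tissue)


def receiver(cid, x, y, radius=10.0):
    return Cell(id=cid, position=np.array([x, y], float), radius=radius,
                role=RECEIVER)


def transport_state(rng, n=12, n_source=4, **kw):
    p = Params(n_init=n, n_source=n_source, **kw)
    return init_cytonemes(seed_tissue(p, rng), p, rng), p


class TestGrowthIncrement:
    def test_degenerate_sigma(self, rng):
        assert sample_growth_increment(2.0, 0.0, rng) == 2.0

    def test_always_positive(self, rng):
        draws = [sample_growth_increment(0.1, 2.0, rng) for _ in range(2000)]
        assert min(draws) > 0

    def test_invalid_parameters(self, rng):
        with pytest.raises(ParameterError):
            sample_growth_increment(0.0, 0.0, rng)
        with pytest.raises(ParameterError):
            sample_growth_increment(-1.0, 1.0, rng)

    def test_truncated_normal_mean_closed_form(self):
        # E[X | X > 0] = mu + sigma * phi(mu/sigma) / Phi(mu/sigma)
        rng = np.random.default_rng(7)
        mu, sigma = 1.0, 2.0
        draws = np.array([sample_growth_increment(mu, sigma, rng)
                          for _ in range(100_000)])
        a = mu / sigma
        expected = mu + sigma * stats.norm.pdf(a) / stats.norm.cdf(a)
        assert abs(draws.mean() - expected) <= 0.02 * expected


class TestCytonemeAngle:
    yolk = make_yolk(300.0)

    def source_at(self, psi, r=310.0):
        return Cell(id=0, position=np.array([r * math.cos(psi), r * math.sin(psi)]),
                    radius=10.0, role=SOURCE)

    def test_degenerate_sigma_gives_tangent(self, rng):
        theta = sample_cytoneme_angle(self.source_at(0.0), self.yolk, 0.0, rng)
        assert theta == pytest.approx(math.pi / 2)  # +x source grows toward +y

    def test_circular_mean_near_tangent(self):
        rng = np.random.default_rng(5)
        src = self.source_at(0.7)
        draws = np.array([sample_cytoneme_angle(src, self.yolk, 0.3, rng)
                          for _ in range(10_000)])
        mean_dir = math.atan2(np.sin(draws).mean(), np.cos(draws).mean())
        assert abs(mean_dir - (0.7 + math.pi / 2)) <= 0.02

    def test_source_at_centre_rejected(self, rng):
        src = Cell(id=0, position=np.zeros(2), radius=10.0, role=SOURCE)
        with pytest.raises(ParameterError):
            sample_cytoneme_angle(src, self.yolk, 0.3, rng)


class TestTipPosition:
    def test_zero_length(self, rng):
        state, p = transport_state(rng)
        cyt = state.cytonemes[0]
        src = state.cell_by_id(cyt.source_id)
        assert np.allclose(tip_position(cyt, state), src.position)

    def test_formula(self, rng):
        state, p = transport_state(rng)
        cyt = state.cytonemes[0]
        src = state.cell_by_id(cyt.source_id)
        src.position = np.array([5.0, 5.0])
        cyt.theta, cyt.length = 0.0, 10.0
        assert np.allclose(tip_position(cyt, state), [15.0, 5.0])

    def test_base_rides_on_source(self, rng):
        state, p = transport_state(rng)
        cyt = state.cytonemes[0]
        cyt.length = 25.0
        before = tip_position(cyt, state)
        delta = np.array([3.0, -4.0])
        src = state.cell_by_id(cyt.source_id)
        src.position = src.position + delta
        assert np.allclose(tip_position(cyt, state), before + delta)


class TestRetraction:
    def test_over_length_always_retracts(self, rng):
        state, p = transport_state(rng, r_retract=0.0)
        cyt = state.cytonemes[0]
        cyt.length = p.L_max + 1
        assert retraction_due(cyt, p, rng)

    def test_empty_tip_retracts(self, rng):
        state, p = transport_state(rng, r_retract=0.0)
        cyt = state.cytonemes[0]
        cyt.tip_wnt = 0.0
        assert retraction_due(cyt, p, rng)

    def test_quiescent_survives(self, rng):
        state, p = transport_state(rng, r_retract=0.0)
        assert not retraction_due(state.cytonemes[0], p, rng)

    def test_replacement_contract(self, rng):
        state, p = transport_state(rng)
        cyt = state.cytonemes[0]
        cyt.length = 30.0
        state.ledger.in_tips -= cyt.tip_wnt - 80.0  # manual tip edit, keep books
        state.ledger.decayed += cyt.tip_wnt - 80.0
        cyt.tip_wnt = 80.0
        decayed0 = state.ledger.decayed
        n0 = len(state.cytonemes)
        new = replace_cytoneme(state, cyt, p, rng)
        state.cytonemes[0] = new
        assert new.length == 0.0 and new.tip_wnt == p.W0 and new.n_deposits == 0
        assert new.id > cyt.id
        assert len(state.cytonemes) == n0
        assert state.ledger.decayed - decayed0 == 80.0
        state.validate()


class TestDetectContact:
    def test_within_radius(self):
        r = receiver(0, 0, 0)
        assert detect_contact((5.0, 0.0), [r]) == 0

    def test_boundary_is_exclusive(self):
        r = receiver(0, 0, 0)
        assert detect_contact((10.0, 0.0), [r]) is None

    def test_nearest_wins(self):
        rs = [receiver(0, 6.0, 0.0), receiver(1, 4.0, 0.0)]
        assert detect_contact((0.0, 0.0), rs) == 1

    def test_dead_and_source_ignored(self):
        dead = receiver(0, 1.0, 0.0)
        dead.alive = False
        src = Cell(id=1, position=np.array([2.0, 0.0]), radius=10.0, role=SOURCE)
        assert detect_contact((0.0, 0.0), [dead, src]) is None

    @pytest.mark.parametrize("seed", range(8))
    def test_kdtree_index_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        rs = [receiver(i, *rng.uniform(0, 60, 2)) for i in range(25)]
        index = _ReceiverIndex(rs)
        for _ in range(50):
            tip = rng.uniform(0, 60, 2)
            brute = detect_contact(tip, rs)
            fast = index.query(tip)
            assert (fast.id if fast is not None else None) == brute


class TestDeposition:
    def test_zero_rate_never_fires(self, rng):
        p = Params(k_dep=0.0)
        assert not any(deposition_fires(p, rng) for _ in range(1000))

    def test_huge_rate_always_fires(self, rng):
        p = Params(k_dep=1e9)
        assert all(deposition_fires(p, rng) for _ in range(100))

    def test_firing_fraction_binomial_bound(self):
        rng = np.random.default_rng(11)
        p = Params(k_dep=30.0, dt=1.0 / 60.0)
        n = 100_000
        fired = sum(deposition_fires(p, rng) for _ in range(n))
        q = 1 - math.exp(-0.5)
        sd = math.sqrt(n * q * (1 - q))
        assert abs(fired - n * q) <= 3 * sd

    def test_full_fraction_single_deposit(self, rng):
        state, p = transport_state(rng, f_dep=1.0)
        cyt = state.cytonemes[0]
        recv = state.alive_receivers()[0]
        deposit(cyt, recv, p, state)
        assert cyt.tip_wnt == 0.0 and recv.wnt == p.W0 and cyt.n_deposits == 1
        with pytest.raises(IntegrityError):
            deposit(cyt, recv, p, state)

    def test_fifth_fraction_five_deposits(self, rng):
        state, p = transport_state(rng, f_dep=0.2)
        cyt = state.cytonemes[0]
        recv = state.alive_receivers()[0]
        for k in range(5):
            ev = deposit(cyt, recv, p, state)
            assert ev.amount == pytest.approx(0.2 * p.W0)
        assert cyt.tip_wnt == pytest.approx(0.0, abs=1e-9)
        assert cyt.n_deposits == 5
        assert recv.wnt == pytest.approx(p.W0)

    def test_tip_plus_receiver_conserved(self, rng):
        state, p = transport_state(rng, f_dep=0.3)
        cyt = state.cytonemes[0]
        recv = state.alive_receivers()[0]
        total0 = cyt.tip_wnt + recv.wnt
        deposit(cyt, recv, p, state)
        assert cyt.tip_wnt + recv.wnt == pytest.approx(total0)
        state.validate()


class TestDecay:
    def test_zero_rate_unchanged(self, rng):
        state, p = transport_state(rng, lambda_decay=0.0)
        recv = state.alive_receivers()[0]
        recv.wnt = 10.0
        state.ledger.loaded_total = state.ledger.in_receivers = 10.0
        decay_receivers(state, p)
        assert recv.wnt == 10.0

    def test_half_life(self, rng):
        state, p = transport_state(rng, lambda_decay=math.log(2), dt=1.0)
        recv = state.alive_receivers()[0]
        recv.wnt = 100.0
        state.ledger.in_receivers += 100.0
        state.ledger.loaded_total += 100.0
        decay_receivers(state, p)
        assert recv.wnt == pytest.approx(50.0)
        state.validate()

    def test_composition_is_analytic(self, rng):
        state, p = transport_state(rng, lambda_decay=0.5)
        recv = state.alive_receivers()[0]
        recv.wnt = 123.0
        state.ledger.loaded_total = state.ledger.in_receivers = 123.0
        for _ in range(60):
            decay_receivers(state, p)
        assert recv.wnt == pytest.approx(123.0 * math.exp(-0.5 * 60 * p.dt), rel=1e-12)


class TestCytonemeStep:
    def test_lengths_increase_without_retraction(self, rng):
        state, p = transport_state(rng, r_retract=0.0, L_max=1e9, k_dep=0.0)
        for _ in range(5):
            before = {c.id: c.length for c in state.cytonemes}
            cytoneme_step(state, p, rng)
            for c in state.cytonemes:
                assert c.length > before[c.id]

    def test_infinite_retraction_replaces_everything(self, rng):
        state, p = transport_state(rng, r_retract=1e9)
        ids0 = {c.id for c in state.cytonemes}
        cytoneme_step(state, p, rng)
        assert len(state.cytonemes) == len(ids0)
        assert ids0.isdisjoint({c.id for c in state.cytonemes})

    def test_deposit_cap_per_fraction(self, rng):
        state, p = transport_state(rng, n=40, n_source=8, f_dep=0.2, k_dep=1e9)
        for _ in range(200):
            cytoneme_step(state, p, rng)
        from collections import Counter
        per_cyt = Counter(e.cytoneme_id for e in state.deposit_log)
        assert per_cyt and max(per_cyt.values()) <= 5

    def test_tip_wnt_never_increases_within_lifetime(self, rng):
        state, p = transport_state(rng, n=40, n_source=8)
        tips = {c.id: c.tip_wnt for c in state.cytonemes}
        for _ in range(100):
            cytoneme_step(state, p, rng)
            for c in state.cytonemes:
                if c.id in tips:
                    assert c.tip_wnt <= tips[c.id]
                tips[c.id] = c.tip_wnt

    def test_lifetimes_exponential_ks(self):
        # Poisson retraction only (no transport, no caps) => Exp(r) lifetimes
        rng = np.random.default_rng(21)
        p = Params(n_init=200, n_source=200, r_retract=3.0, dt=0.004,
                   L_max=1e12, k_dep=0.0, mu_g=0.1, sigma_g=0.0)
        state = init_cytonemes(seed_tissue(p, rng), p, rng)
        # collect lifetimes only for cytonemes born early, and run far past the
        # birth window, so the sample is not censored toward short lifetimes
        birth_window, horizon = 800, 2200  # ~26 mean lifetimes past the window
        born = {c.id: 0 for c in state.cytonemes}
        lifetimes = []
        for step in range(1, horizon + 1):
            cytoneme_step(state, p, rng)
            alive = {c.id for c in state.cytonemes}
            for cid in set(born) - alive:
                b = born.pop(cid)
                if b <= birth_window:
                    lifetimes.append((step - b) * p.dt)
            for cid in alive - set(born):
                born[cid] = step
        assert len(lifetimes) >= 10_000
        stat = stats.kstest(lifetimes, stats.expon(scale=1 / 3.0).cdf)
        assert stat.pvalue > 0.01
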