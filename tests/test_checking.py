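import numpy as np
import pytest

from dsdmc.dsd_core import expand_modules, parse_system
from dsdmc.network import build_network
from dsdmc.ctmc import build_ctmc
from dsdmc.checking import (
    SolverError,
    absorption_distribution,
    check_deadlock_invariant,
    check_reachable,
    expected_time_to,
    find_deadlocks,
    prob_reach,
    prob_reach_within,
)
from dsdmc import gate_library as gl


def simple_model(src):
    spec = expand_modules(parse_system(src))
    net = build_network(spec)
    return build_ctmc(net, spec)


@pytest.fixture(scope="module")
def one_step_model():
    # single irreversible displacement: A + B -> C + D
    return simple_model("<t^ x u^> | {t^*}[x]{u^*}")


class TestDeadlocks:
    def test_faulty_pair_has_two(self, faulty_pair_model):
        assert len(find_deadlocks(faulty_pair_model)) == 2

    def test_reaction_free_model(self):
        m = simple_model("<t^ x>")
        assert find_deadlocks(m) == {0}

    def test_corrected_pair_deadlocks_all_done(self, fixed_pair_model):
        m = fixed_pair_model
        done = m.eval_label("all_done")
        for d in find_deadlocks(m):
            assert done[d]


class TestCTL:
    def test_faulty_pair_invariant_fails_with_witness(self, faulty_pair_model):
        m = faulty_pair_model
        done = m.eval_label("all_done")
        res = check_deadlock_invariant(m, m.deadlocks() <= done)
        assert res.value is False
        assert res.witness is not None
        # witness ends in a deadlock violating the predicate
        final = res.witness[-1]
        idx = m.state_index()[final]
        assert m.deadlocks()[idx] and not done[idx]

    def test_trivial_predicate(self, faulty_pair_model):
        m = faulty_pair_model
        assert check_deadlock_invariant(m, np.ones(m.n_states, bool)).value is True

    def test_corrected_pair_both_queries(self, fixed_pair_model):
        m = fixed_pair_model
        done = m.eval_label("all_done")
        assert check_deadlock_invariant(m, ~m.deadlocks() | done).value is True
        assert check_reachable(m, done).value is True

    def test_reachable_false(self, faulty_pair_model):
        m = faulty_pair_model
        assert check_reachable(m, np.zeros(m.n_states, bool)).value is False


class TestProbReach:
    def test_faulty_pair_fifty_fifty(self, faulty_pair_model):
        m = faulty_pair_model
        done = m.eval_label("all_done")
        dead = m.deadlocks()
        p_ok = prob_reach(m, dead & done).value
        p_err = prob_reach(m, dead & ~done).value
        assert p_ok == pytest.approx(0.5, abs=1e-9)
        assert p_err == pytest.approx(0.5, abs=1e-9)

    def test_against_dense_oracle(self, faulty_pair_model):
        # independent dense linear-algebra solve of the reachability system
        m = faulty_pair_model
        done = m.eval_label("all_done")
        target = m.deadlocks() & done
        P = m.embedded_jump_matrix().toarray()
        n = m.n_states
        A = np.eye(n) - P
        for i in np.nonzero(target)[0]:
            A[i] = 0.0
            A[i, i] = 1.0
        b = target.astype(float)
        x = np.linalg.solve(A, b)
        assert prob_reach(m, target).value == pytest.approx(x[m.initial], abs=1e-8)


class TestTimeBounded:
    def test_t_zero(self, faulty_pair_model):
        m = faulty_pair_model
        done = m.eval_label("all_done")
        assert prob_reach_within(m, done, 0.0).value == 0.0
        everything = np.ones(m.n_states, bool)
        assert prob_reach_within(m, everything, 0.0).value == 1.0

    def test_monotone_and_converges(self, faulty_pair_model):
        m = faulty_pair_model
        done = m.eval_label("all_done")
        times = [1e3, 1e4, 1e5, 1e6]
        vals = [prob_reach_within(m, done, t).value for t in times]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(prob_reach(m, done).value, abs=1e-6)


class TestExpectedTime:
    def test_exponential_mean(self, one_step_model):
        m = one_step_model
        target = m.exit_rates == 0.0
        rate = m.exit_rates[m.initial]
        res = expected_time_to(m, target)
        assert res.value == pytest.approx(1.0 / rate)

    def test_infinite_expectation_reported(self, faulty_pair_model):
        m = faulty_pair_model
        done = m.eval_label("all_done")
        with pytest.raises(SolverError, match="infinite"):
            expected_time_to(m, m.deadlocks() & done)

    def test_chain_increasing_affine(self):
        times = []
        for k in (1, 2, 3):
            spec = gl.transducer_chain(k, 1, "T2")
            net = build_network(spec)
            m = build_ctmc(net, spec, label_config=gl.transducer_labels(1, output=f"x{k}"))
            times.append(expected_time_to(m, m.eval_label("all_done")).value)
        diffs = np.diff(times)
        assert (diffs > 0).all()
        assert np.ptp(diffs) / diffs.mean() < 0.05


class TestAbsorption:
    def test_probabilities_sum_to_one(self, faulty_pair_model):
        res = absorption_distribution(faulty_pair_model)
        dist = res.diagnostics["distribution"]
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)
        assert set(dist) == find_deadlocks(faulty_pair_model)

    def test_reactive_gate_percentage_decreases(self):
        pct = []
        for n in (1, 2):
            spec = gl.transducer_pair(n, "T")
            net = build_network(spec)
            m = build_ctmc(net, spec, label_config=gl.transducer_labels(n))
            gr = m.eval_label("gates_reactive")
            dist = absorption_distribution(m).diagnostics["distribution"]
            pct.append(sum(p * gr[d] for d, p in dist.items()) / (4 * n))
        assert pct[1] < pct[0]

    def test_non_deadlock_recurrent_class_detected(self):
        # no-GC catalyst cycles forever through spent-gate re-entries
        spec = gl.catalyst_system(1, gc=False)
        net = build_network(spec)
        m = build_ctmc(net, spec)
        with pytest.raises(SolverError, match="recurrent"):
            absorption_distribution(m)


class TestRateRescaling:
    def test_invariance_and_time_scaling(self):
        from dsdmc.reduction import RateModel

        spec = gl.transducer_pair(1, "T2")
        vals = {}
        for c in (1.0, 10.0):
            net = build_network(spec, RateModel(bind=3e-4 * c))
            m = build_ctmc(net, spec, label_config=gl.transducer_labels(1))
            done = m.eval_label("all_done")
            vals[c] = (
                prob_reach(m, done).value,
                expected_time_to(m, done).value,
            )
        assert vals[1.0][0] == pytest.approx(vals[10.0][0], abs=1e-9)
        assert vals[1.0][1] == pytest.approx(10.0 * vals[10.0][1], rel=1e-9)
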