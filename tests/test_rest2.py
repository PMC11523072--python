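"""Lambda ladders, topology scaling, exchange bookkeeping."""

import math

import numpy as np
import pytest

from macronoe.rest2 import (ExchangeRecord, effective_temperature,
                            exchange_acceptance, exchange_statistics,
                            exponential_lambdas, parse_topology,
                            quadratic_lambdas, scale_topology, write_topology)

TOY_TOP = """\
[ defaults ]
1 3 yes 0.5 0.8333
[ atomtypes ]
; name at.num mass charge ptype sigma epsilon
CT 6 12.011 0.0 A 0.35 0.4577
HW 1 1.008 0.0 A 0.2 0.05
OW 8 15.999 0.0 A 0.315 0.636
[ moleculetype ]
MOL 3
[ atoms ]
1 CT 1 MOL C1 1 0.4
2 CT 1 MOL C2 2 -0.2
3 CT 1 MOL C3 3 -0.1
4 CT 1 MOL C4 4 -0.1
[ bonds ]
1 2 1 0.15 250000
2 3 1 0.15 250000
3 4 1 0.15 250000
[ pairs ]
1 4 1
[ angles ]
1 2 3 1 111.0 400.0
2 3 4 1 111.0 400.0
[ dihedrals ]
1 2 3 4 9 0.0 10.0 3
1 2 3 4 4 180.0 4.0 2
[ moleculetype ]
SOL 2
[ atoms ]
1 OW 1 SOL OW 1 -0.8
2 HW 1 SOL HW1 1 0.4
3 HW 1 SOL HW2 1 0.4
[ bonds ]
1 2 1 0.1 300000
1 3 1 0.1 300000
[ angles ]
2 1 3 1 104.5 300.0
[ system ]
toy box
[ molecules ]
MOL 1
SOL 3
"""


@pytest.fixture
def toy_top():
    return parse_topology(TOY_TOP.splitlines())


class TestLadders:
    @pytest.mark.parametrize("make", [exponential_lambdas, quadratic_lambdas])
    def test_endpoints_and_monotonicity(self, make):
        s = make(12, 0.125)
        assert s[0] == pytest.approx(1.0, abs=1e-15)
        assert s[11] == pytest.approx(0.125, abs=1e-12)
        assert all(a > b for a, b in zip(s, list(s)[1:]))

    def test_exponential_hand_example(self):
        assert list(exponential_lambdas(3, 0.25)) == pytest.approx([1.0, 0.5, 0.25])
        assert list(exponential_lambdas(2, 0.5)) == pytest.approx([1.0, 0.5])

    def test_quadratic_hand_example(self):
        # sqrt(f)=0.5 -> midpoint sqrt(lambda)=0.75 -> lambda=0.5625
        assert list(quadratic_lambdas(3, 0.25)) == pytest.approx([1.0, 0.5625, 0.25])

    def test_quadratic_sqrt_linear_in_index(self):
        for n, f in [(6, 0.125), (12, 0.125), (5, 0.3)]:
            roots = np.sqrt(quadratic_lambdas(n, f).lambdas)
            second_diff = np.diff(roots, 2)
            assert np.all(np.abs(second_diff) < 1e-12)

    def test_quadratic_dominates_exponential_inside(self):
        for n, f in [(4, 0.125), (8, 0.2), (12, 0.125), (6, 0.5)]:
            q = quadratic_lambdas(n, f)
            e = exponential_lambdas(n, f)
            assert all(q[i] >= e[i] - 1e-12 for i in range(n))
            assert any(q[i] > e[i] + 1e-9 for i in range(1, n - 1))

    @pytest.mark.parametrize("n, f", [(1, 0.5), (12, 0.0), (12, 1.0), (12, -1)])
    def test_invalid_arguments(self, n, f):
        with pytest.raises(ValueError):
            exponential_lambdas(n, f)
        with pytest.raises(ValueError):
            quadratic_lambdas(n, f)


class TestEffectiveTemperature:
    @pytest.mark.parametrize("lam, t", [(1.0, 300.0), (0.5, 600.0), (0.125, 2400.0)])
    def test_values(self, lam, t):
        assert effective_temperature(lam) == pytest.approx(t)

    def test_nonpositive_lambda_raises(self):
        with pytest.raises(ValueError):
            effective_temperature(0.0)


class TestScaleTopology:
    def test_lambda_one_is_identity(self, toy_top):
        assert scale_topology(toy_top, 1.0, solute="MOL") == toy_top

    def test_charge_epsilon_dihedral_scaling(self, toy_top):
        scaled = scale_topology(toy_top, 0.25, solute="MOL")
        mol = scaled.moleculetype("MOL")
        assert mol.atoms[0]["charge"] == pytest.approx(0.4 * 0.5)  # sqrt(0.25)
        assert scaled.atomtypes["CT_s"]["epsilon"] == pytest.approx(0.4577 * 0.25)
        assert scaled.atomtypes["CT"]["epsilon"] == pytest.approx(0.4577)
        # both proper (funct 9) and improper (funct 4) barrier heights scale
        assert mol.dihedrals[0]["params"][1] == pytest.approx(10.0 * 0.25)
        assert mol.dihedrals[1]["params"][1] == pytest.approx(4.0 * 0.25)

    def test_angles_only_with_flag_and_bonds_never(self, toy_top):
        lam = 0.125
        plain = scale_topology(toy_top, lam, solute="MOL")
        angled = scale_topology(toy_top, lam, solute="MOL", include_angles=True)
        assert plain.moleculetype("MOL").angles[0]["params"][1] == pytest.approx(400.0)
        assert angled.moleculetype("MOL").angles[0]["params"][1] == \
            pytest.approx(400.0 * lam)
        for top in (plain, angled):
            assert top.moleculetype("MOL").bonds[0]["params"] == [0.15, 250000.0]
            # geometry parameters untouched
            assert top.moleculetype("MOL").angles[0]["params"][0] == 111.0
            assert top.moleculetype("MOL").dihedrals[0]["params"][0] == 0.0

    def test_solvent_untouched(self, toy_top):
        scaled = scale_topology(toy_top, 0.125, solute="MOL")
        sol = scaled.moleculetype("SOL")
        ref = toy_top.moleculetype("SOL")
        assert sol == ref
        assert scaled.atomtypes["OW"] == toy_top.atomtypes["OW"]

    def test_semigroup_property(self, toy_top):
        twice = scale_topology(scale_topology(toy_top, 0.5, solute="MOL"),
                               0.25, solute="MOL")
        once = scale_topology(toy_top, 0.125, solute="MOL")
        m2, m1 = twice.moleculetype("MOL"), once.moleculetype("MOL")
        for a2, a1 in zip(m2.atoms, m1.atoms):
            assert a2["charge"] == pytest.approx(a1["charge"], rel=1e-12)
        assert twice.atomtypes["CT_s"]["epsilon"] == \
            pytest.approx(once.atomtypes["CT_s"]["epsilon"], rel=1e-12)
        for d2, d1 in zip(m2.dihedrals, m1.dihedrals):
            assert d2["params"] == pytest.approx(d1["params"], rel=1e-12)

    def test_write_parse_roundtrip_field_identical(self, toy_top, tmp_path):
        scaled = scale_topology(toy_top, 0.125, solute="MOL", include_angles=True)
        path = tmp_path / "scaled.top"
        write_topology(scaled, path)
        assert parse_topology(path) == scaled

    def test_bad_lambda_and_missing_solute(self, toy_top):
        with pytest.raises(ValueError):
            scale_topology(toy_top, 0.0, solute="MOL")
        with pytest.raises(KeyError):
            scale_topology(toy_top, 0.5, solute="NOPE")


class TestExchangeAcceptance:
    @pytest.mark.parametrize("delta, p", [
        (0.0, 1.0), (math.log(2), 0.5), (-5.0, 1.0)])
    def test_metropolis_values(self, delta, p):
        assert exchange_acceptance(delta) == pytest.approx(p, rel=1e-12)

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            exchange_acceptance(float("nan"))


class TestExchangeStatistics:
    @staticmethod
    def make_records(n, plan):
        """plan: list of (pair, accepted). Assignments built consistently."""
        state = list(range(n))  # config -> slot
        records = []
        for t, (pair, acc) in enumerate(plan):
            if acc:
                ci = state.index(pair[0])
                cj = state.index(pair[1])
                state[ci], state[cj] = pair[1], pair[0]
            records.append(ExchangeRecord(t, pair, acc, tuple(state)))
        return records

    def test_all_accepted_rates_one(self):
        recs = self.make_records(3, [((0, 1), True), ((1, 2), True)] * 5)
        stats = exchange_statistics(recs, n_replicas=3)
        assert stats["rates"] == {(0, 1): 1.0, (1, 2): 1.0}
        assert stats["spread"] == 0.0

    def test_partial_acceptance_rate(self):
        plan = [((0, 1), i < 3) for i in range(10)]
        stats = exchange_statistics(self.make_records(2, plan), n_replicas=2)
        assert stats["rates"][(0, 1)] == pytest.approx(0.3)

    def test_demux_rows_are_permutations(self):
        rng = np.random.default_rng(11)
        plan = [((int(i), int(i) + 1), bool(rng.integers(2)))
                for i in rng.integers(0, 3, size=50)]
        stats = exchange_statistics(self.make_records(4, plan), n_replicas=4)
        for row in stats["demux"]:
            assert sorted(row) == [0, 1, 2, 3]

    def test_inconsistent_history_detected(self):
        recs = [ExchangeRecord(0, (0, 1), True, (0, 1, 2))]  # claims no swap
        with pytest.raises(ValueError, match="inconsistent"):
            exchange_statistics(recs, n_replicas=3)

    def test_non_neighbor_pair_rejected(self):
        recs = [ExchangeRecord(0, (0, 2), False, (0, 1, 2))]
        with pytest.raises(ValueError, match="neighbor"):
            exchange_statistics(recs, n_replicas=3)
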