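import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grnforge import (
    GRN,
    assign_parameters,
    combined_regulation,
    hill,
    ode_rhs,
    regulation_input,
)
from grnforge.kinetics import (
    ALPHA_STRONG,
    ALPHA_WEAK,
    K_RANGE,
    KineticParameters,
    KineticsError,
    LAMBDA_MRNA_RANGE,
    LAMBDA_PROT_RANGE,
    N_CHOICES,
    RegulatorGroup,
    make_rhs,
)


class TestHill:
    def test_half_saturation(self):
        assert hill(0.4, k=0.4, n=3, alpha=0.9, sign=1) == pytest.approx(0.45)

    def test_boundaries_at_zero(self):
        assert hill(0.0, 0.3, 2, 0.7, sign=1) == 0.0
        assert hill(0.0, 0.3, 2, 0.7, sign=-1) == 0.7

    def test_hand_computed_value(self):
        # (0.8/0.4)^2 = 4; 0.8 * 4/5 = 0.64
        assert hill(0.8, k=0.4, n=2, alpha=0.8, sign=1) == pytest.approx(0.64)

    def test_negative_concentration_rejected(self):
        with pytest.raises(KineticsError):
            hill(-0.1, 0.3, 2, 0.5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        k=st.floats(0.2, 0.6),
        n=st.integers(2, 4),
        alpha=st.floats(0.1, 1.0),
    )
    def test_monotone_and_bounded(self, k, n, alpha):
        ys = np.linspace(0, 5, 200)
        act = np.array([hill(y, k, n, alpha, 1) for y in ys])
        rep = np.array([hill(y, k, n, alpha, -1) for y in ys])
        assert np.all(np.diff(act) >= 0)
        assert np.all(np.diff(rep) <= 0)
        assert np.all((act >= 0) & (act <= alpha))
        assert np.all((rep >= 0) & (rep <= alpha))


class TestCombinedRegulation:
    def test_absent_second_regulator_reduces_to_hill(self):
        group = RegulatorGroup(
            target=0, regulators=[1, 2], alpha=[0.5, 0.3],
            k=[0.4, 0.3], n=[2, 3], sign=1, P=0,
        )
        got = combined_regulation([0.8, 0.0], group)
        assert got == pytest.approx(hill(0.8, 0.4, 2, 0.5, 1))

    def test_hand_computed_and_case(self):
        # V1 = V2 = 1 at y = k: (0.3 + 0.3 + 0.8) / (1+1+1+1) = 0.35
        group = RegulatorGroup(
            target=0, regulators=[1, 2], alpha=[0.3, 0.3],
            k=[0.5, 0.2], n=[2, 4], sign=1, P=1, alpha3=0.8,
        )
        assert combined_regulation([0.5, 0.2], group) == pytest.approx(0.35)

    def test_or_logic_equals_shared_denominator_sum(self):
        """P=0 must equal sum(alpha_i V_i) / (1 + sum V_i), evaluated directly."""
        rng = np.random.default_rng(5)
        for n_reg in (2, 3):
            alpha = rng.uniform(0.2, 1.0, n_reg)
            k = rng.uniform(0.2, 0.6, n_reg)
            n = rng.integers(2, 5, n_reg)
            y = rng.uniform(0, 2, n_reg)
            group = RegulatorGroup(
                target=0, regulators=list(range(1, n_reg + 1)),
                alpha=alpha.tolist(), k=k.tolist(), n=n.tolist(), sign=1, P=0,
            )
            v = (y / k) ** n
            expected = np.dot(alpha, v) / (1 + v.sum())
            assert combined_regulation(y, group) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounded_by_max_alpha(self, seed):
        rng = np.random.default_rng(seed)
        n_reg = int(rng.integers(1, 4))
        group = RegulatorGroup(
            target=0, regulators=list(range(n_reg)),
            alpha=rng.uniform(0.1, 1.0, n_reg).tolist(),
            k=rng.uniform(0.2, 0.6, n_reg).tolist(),
            n=rng.integers(2, 5, n_reg).tolist(),
            sign=1, P=int(rng.integers(2)), alpha3=float(rng.uniform(0.1, 1.0)),
        )
        y = rng.uniform(0, 10, n_reg)
        val = combined_regulation(y, group)
        assert 0 <= val <= max(max(group.alpha), group.alpha3) + 1e-12


class TestAssignParameters:
    def test_ranges_honoured(self, small_grn):
        p = assign_parameters(small_grn, combo_probability=0.5, seed=0)
        assert np.all(p.m == 1)
        assert np.all((p.lambda_mrna >= LAMBDA_MRNA_RANGE[0])
                      & (p.lambda_mrna <= LAMBDA_MRNA_RANGE[1]))
        assert np.all((p.lambda_prot >= LAMBDA_PROT_RANGE[0])
                      & (p.lambda_prot <= LAMBDA_PROT_RANGE[1]))
        for g in p.groups:
            assert all(K_RANGE[0] <= k <= K_RANGE[1] for k in g.k)
            assert all(n in N_CHOICES for n in g.n)
            assert all(0 < a <= 1 for a in g.alpha)

    def test_median_split_alpha_classes(self):
        # two edges, |w| = 0.2 and 0.9; median 0.55: only the 0.9 edge is strong
        w = np.zeros((3, 3))
        w[1, 0] = 0.2
        w[2, 0] = 0.9
        grn = GRN(genes=["A", "B", "C"], weights=w)
        for seed in range(20):
            p = assign_parameters(grn, combo_probability=0.0, seed=seed)
            for g in p.groups:
                lo, hi = ALPHA_STRONG if g.target == 2 else ALPHA_WEAK
                assert lo <= g.alpha[0] <= hi

    def test_single_edge_is_weak(self):
        # |w| = 0.9 equals the median, hence not greater: weak class
        w = np.zeros((2, 2))
        w[1, 0] = 0.9
        grn = GRN(genes=["A", "B"], weights=w)
        for seed in range(20):
            (g,) = assign_parameters(grn, seed=seed).groups
            assert ALPHA_WEAK[0] <= g.alpha[0] <= ALPHA_WEAK[1]

    def test_zero_combo_probability_only_singletons(self, small_grn):
        p = assign_parameters(small_grn, combo_probability=0.0, seed=1)
        assert all(len(g.regulators) == 1 and g.P == 0 for g in p.groups)

    def test_opposing_signs_never_grouped(self):
        w = np.zeros((3, 3))
        w[2, 0] = 0.5  # A activates C
        w[2, 1] = -0.5  # B represses C
        grn = GRN(genes=["A", "B", "C"], weights=w)
        for seed in range(10):
            p = assign_parameters(grn, combo_probability=1.0, seed=seed)
            assert all(len(g.regulators) == 1 for g in p.groups)

    def test_combo_groups_get_weak_members_strong_alpha3(self):
        w = np.zeros((3, 3))
        w[2, 0] = 0.5
        w[2, 1] = 0.6
        grn = GRN(genes=["A", "B", "C"], weights=w)
        p = assign_parameters(grn, combo_probability=1.0, seed=3)
        (g,) = [g for g in p.groups if len(g.regulators) == 2]
        assert g.P == 1
        assert all(0.2 <= a <= 0.4 for a in g.alpha)
        assert 0.7 <= g.alpha3 <= 1.0

    def test_reproducible_bit_exact(self, small_grn):
        a = assign_parameters(small_grn, combo_probability=0.3, seed=42)
        b = assign_parameters(small_grn, combo_probability=0.3, seed=42)
        np.testing.assert_array_equal(a.lambda_mrna, b.lambda_mrna)
        assert a.to_dict() == b.to_dict()

    def test_empty_network_rejected(self):
        grn = GRN(genes=["A", "B"], weights=np.zeros((2, 2)))
        with pytest.raises(KineticsError):
            assign_parameters(grn, seed=0)

    def test_yaml_round_trip(self, tmp_path, small_params):
        path = tmp_path / "params.yaml"
        small_params.save(path)
        back = KineticParameters.load(path)
        assert back.to_dict() == small_params.to_dict()


class TestOdeRhs:
    def test_isolated_gene_fixed_point(self, isolated_gene_params):
        # m=1, lambda_mrna=0.5, x=2 is the mRNA fixed point (basal f = 1)
        d = ode_rhs(np.array([2.0, 8.0]), isolated_gene_params)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_dead_system(self, isolated_gene_params):
        p = isolated_gene_params
        p.m = np.array([0.0])
        d = ode_rhs(np.zeros(2), p)
        np.testing.assert_allclose(d, 0.0)

    def test_protein_fixed_point_relation(self, isolated_gene_params):
        # dy/dt = 0 exactly at y* = r x / lambda_prot for any x
        x = 3.7
        y_star = 1.0 * x / 0.25
        d = ode_rhs(np.array([x, y_star]), isolated_gene_params)
        assert d[1] == pytest.approx(0.0, abs=1e-12)

    def test_dimension_mismatch_rejected(self, isolated_gene_params):
        with pytest.raises(KineticsError):
            ode_rhs(np.zeros(3), isolated_gene_params)

    def test_make_rhs_matches_ode_rhs(self, small_params):
        rng = np.random.default_rng(0)
        rhs = make_rhs(small_params)
        for _ in range(10):
            state = rng.uniform(0, 2, 2 * small_params.n_genes)
            np.testing.assert_allclose(
                rhs(0.0, state), ode_rhs(state, small_params), rtol=1e-12
            )

    def test_unregulated_gene_has_basal_f_one(self, small_params):
        y = np.random.default_rng(1).uniform(0, 2, small_params.n_genes)
        f = regulation_input(y, small_params)
        regulated = {g.target for g in small_params.groups}
        for i in range(small_params.n_genes):
            if i not in regulated:
                assert f[i] == 1.0
        assert np.all((f >= 0) & (f <= 1))
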