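import numpy as np
import pytest

from grnforge import GRN, assign_parameters, generate_network
from grnforge.kinetics import KineticParameters, RegulatorGroup


@pytest.fixture
def triangle_ffl() -> GRN:
    """A -> B, A -> C, B -> C: exactly one feed-forward loop."""
    w = np.zeros((3, 3))
    w[1, 0] = 0.5  # A -> B
    w[2, 0] = 0.5  # A -> C
    w[2, 1] = 0.5  # B -> C
    return GRN(genes=["A", "B", "C"], weights=w)


@pytest.fixture
def three_cycle() -> GRN:
    """A -> B -> C -> A."""
    w = np.zeros((3, 3))
    w[1, 0] = 1.0
    w[2, 1] = 1.0
    w[0, 2] = 1.0
    return GRN(genes=["A", "B", "C"], weights=w)


@pytest.fixture
def small_grn() -> GRN:
    return generate_network(20, 2.0, ffl_weight=0.5, seed=11)


@pytest.fixture
def small_params(small_grn):
    return assign_parameters(small_grn, combo_probability=0.3, seed=12)


@pytest.fixture
def isolated_gene_params():
    """One unregulated gene: m=1, lambda_mrna=0.5, r=1, lambda_prot=0.25.

    Closed-form fixed point: x* = m/lambda_mrna = 2, y* = r x*/lambda_prot = 8.
    """
    return KineticParameters(
        genes=["G"],
        m=np.array([1.0]),
        r=np.array([1.0]),
        lambda_mrna=np.array([0.5]),
        lambda_prot=np.array([0.25]),
        groups=[],
    )


def random_dag_grn(n: int, rng: np.random.Generator, p_edge: float = 0.25) -> GRN:
    """Random acyclic GRN: edges only from lower to higher index."""
    w = np.zeros((n, n))
    for t in range(n):
        for r in range(t):
            if rng.random() < p_edge:
                mag = rng.uniform(0.1, 1.0)
                w[t, r] = mag if rng.random() < 0.7 else -mag
    if not w.any():  # guarantee at least one edge
        w[1, 0] = 0.5
    return GRN(genes=[f"g{i}" for i in range(n)], weights=w)


def analytic_acyclic_fixed_point(params: KineticParameters) -> np.ndarray:
    """Cascade fixed point of an acyclic system, solved in topological order.

    Independent oracle: evaluates the regulation algebra directly from the
    group parameters with plain arithmetic (no ODE integration).
    x* = m * f(y*_regulators) / lambda_mrna, y* = r x* / lambda_prot.
    """
    n = params.n_genes
    children: dict[int, list[RegulatorGroup]] = {}
    indeg = np.zeros(n, dtype=int)
    for g in params.groups:
        children.setdefault(g.target, []).append(g)
        indeg[g.target] += 0  # groups share targets; real deps below
    deps = {t: set() for t in range(n)}
    for g in params.groups:
        deps[g.target].update(g.regulators)
    order, placed = [], set()
    while len(order) < n:
        progressed = False
        for t in range(n):
            if t not in placed and deps[t] <= placed:
                order.append(t)
                placed.add(t)
                progressed = True
        assert progressed, "system is not acyclic"
    x = np.zeros(n)
    y = np.zeros(n)
    for t in order:
        grps = children.get(t, [])
        if not grps:
            f = 1.0
        else:
            contribs = []
            for g in grps:
                v = (y[g.regulators] / np.asarray(g.k)) ** np.asarray(g.n)
                num = float(np.dot(g.alpha, v))
                den = 1.0 + float(v.sum())
                if g.P == 1:
                    prod = float(np.prod(v))
                    num += g.alpha3 * prod
                    den += prod
                val = num / den
                contribs.append(val if g.sign == 1 else 1.0 - val)
            f = min(1.0, max(0.0, float(np.mean(contribs))))
        x[t] = params.m[t] * f / params.lambda_mrna[t]
        y[t] = params.r[t] * x[t] / params.lambda_prot[t]
    return np.concatenate([x, y])
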