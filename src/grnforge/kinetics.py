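"""Kinetic parameters and the two-step transcription/translation ODE.

The expression of gene *i* is modelled as a pair of coupled ODEs:

    dx_i/dt = m_i * f(y_reg) - lambda_mrna_i * x_i        (mRNA)
    dy_i/dt = r_i * x_i      - lambda_prot_i * y_i        (protein)

where ``x`` is mRNA concentration, ``y`` protein concentration, ``m_i``
the maximum transcription rate (1 for unperturbed genes), ``r_i`` the
maximum translation rate, and the lambdas first-order degradation
constants.  Regulation enters through ``f``, built from Hill functions
of the regulators' protein concentrations:

    hill_act(y)  = alpha * (y/k)^n / (1 + (y/k)^n)
    hill_rep(y)  = alpha / (1 + (y/k)^n)

with alpha the regulatory strength, k the dissociation constant and n
the Hill coefficient.  Two or more same-sign regulators may act as a
combinatorial group through a shared-denominator additive Hill form
(with V_i = (y_i/k_i)^n_i):

    f_group = (sum_i alpha_i V_i + alpha3 * P * prod_i V_i)
              / (1 + sum_i V_i + P * prod_i V_i)

P = 1 adds the top-order product term (AND logic: the combination fires
only when all members are present); P = 0 is purely additive (OR).

Aggregation and conventions chosen here (the combinatorial form above
covers one group; the cross-group rule must be fixed by the
implementation):

- A gene with no regulators transcribes at its basal maximum, f = 1.
- Each independent edge is a group of size one; per target, activator
  groups contribute their group value directly while each repressor
  group contributes ``1 - (group value evaluated in activation form)``,
  i.e. full transcription when the repressor is absent, reduced by up to
  alpha when saturated.
- f for the target is the arithmetic mean of its group contributions,
  clamped to [0, 1], so m_i remains the true maximum rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .network import GRN

__all__ = [
    "KineticParameters",
    "RegulatorGroup",
    "KineticsError",
    "assign_parameters",
    "hill",
    "combined_regulation",
    "regulation_input",
    "ode_rhs",
]

# sampling ranges for the randomly assigned constants
LAMBDA_MRNA_RANGE = (0.2, 0.7)
LAMBDA_PROT_RANGE = (0.2, 0.4)
K_RANGE = (0.2, 0.6)
N_CHOICES = (2, 3, 4)
ALPHA_STRONG = (0.6, 1.0)
ALPHA_WEAK = (0.4, 0.8)
ALPHA_COMBO_MEMBER = (0.2, 0.4)
ALPHA_COMBO_GROUP = (0.7, 1.0)
# Translation rate range, chosen so unperturbed protein steady states
# (y* = r x*/lambda_prot with x* up to m/lambda_mrna) land near the
# dissociation constants k in [0.2, 0.6]: regulation then operates on the
# sensitive part of the Hill curve instead of its saturated plateau.
R_RANGE = (0.1, 0.3)


class KineticsError(ValueError):
    """Invalid kinetic parameterisation."""


@dataclass
class RegulatorGroup:
    """One regulatory term of a target gene.

    Independent edges are groups of size one with ``P = 0``;
    combinatorial groups have two or more members, ``P = 1`` and a group
    strength ``alpha3`` for the product term.  All members share `sign`
    (+1 activation, -1 repression).
    """

    target: int
    regulators: list[int]
    alpha: list[float]
    k: list[float]
    n: list[int]
    sign: int
    P: int = 0
    alpha3: float = 0.0

    def __post_init__(self) -> None:
        if not self.regulators:
            raise KineticsError("empty regulator group")
        if self.P not in (0, 1):
            raise KineticsError(f"P must be 0 or 1, got {self.P}")
        if self.sign not in (-1, 1):
            raise KineticsError(f"sign must be +1 or -1, got {self.sign}")


@dataclass
class KineticParameters:
    """Full kinetic parameterisation of a GRN's ODE system."""

    genes: list[str]
    m: np.ndarray
    r: np.ndarray
    lambda_mrna: np.ndarray
    lambda_prot: np.ndarray
    groups: list[RegulatorGroup]
    metadata: dict = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def groups_of(self, target: int) -> list[RegulatorGroup]:
        return [g for g in self.groups if g.target == target]

    # -- serialisation: flat key-value document for exact reproduction --
    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "m": self.m.tolist(),
            "r": self.r.tolist(),
            "lambda_mrna": self.lambda_mrna.tolist(),
            "lambda_prot": self.lambda_prot.tolist(),
            "groups": [
                {
                    "target": g.target,
                    "regulators": list(g.regulators),
                    "alpha": list(g.alpha),
                    "k": list(g.k),
                    "n": list(g.n),
                    "sign": g.sign,
                    "P": g.P,
                    "alpha3": g.alpha3,
                }
                for g in self.groups
            ],
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        return cls(
            genes=list(d["genes"]),
            m=np.asarray(d["m"], dtype=float),
            r=np.asarray(d["r"], dtype=float),
            lambda_mrna=np.asarray(d["lambda_mrna"], dtype=float),
            lambda_prot=np.asarray(d["lambda_prot"], dtype=float),
            groups=[RegulatorGroup(**g) for g in d["groups"]],
            metadata=d.get("metadata", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "KineticParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def assign_parameters(
    grn: GRN, combo_probability: float = 0.2, seed: int | None = None
) -> KineticParameters:
    """Draw kinetic constants for a GRN.

    Per gene: ``m = 1`` (unperturbed maximum transcription rate),
    ``lambda_mrna ~ U[0.2, 0.7]``, ``lambda_prot ~ U[0.2, 0.4]``,
    ``r ~ U[0.1, 0.3]``.  Per edge: ``k ~ U[0.2, 0.6]``, ``n`` uniform on
    {2, 3, 4}, and alpha split on the network's median absolute edge
    weight — strong interactions (|w| above the median) get
    ``alpha ~ U[0.6, 1.0]``, weak ones ``alpha ~ U[0.4, 0.8]``.

    For each target with two or more same-sign regulators, with
    probability `combo_probability` those regulators form one
    combinatorial group (P = 1): each member's alpha is redrawn weak,
    ``U[0.2, 0.4]``, and the group gets a strong joint strength
    ``alpha3 ~ U[0.7, 1.0]``.  Activators and repressors are never mixed
    in one group.
    """
    edges = grn.edges()
    if not edges:
        raise KineticsError("cannot assign kinetics to a network with no edges")
    rng = np.random.default_rng(seed)
    n = grn.n_genes
    m = np.ones(n)
    r = rng.uniform(*R_RANGE, size=n)
    lam_m = rng.uniform(*LAMBDA_MRNA_RANGE, size=n)
    lam_p = rng.uniform(*LAMBDA_PROT_RANGE, size=n)

    abs_w = np.abs([grn.weights[t, reg] for t, reg in edges])
    median_w = float(np.median(abs_w))

    def draw_edge(t: int, reg: int) -> tuple[float, float, int, int]:
        w = grn.weights[t, reg]
        lo, hi = ALPHA_STRONG if abs(w) > median_w else ALPHA_WEAK
        alpha = rng.uniform(lo, hi)
        k = rng.uniform(*K_RANGE)
        hill_n = int(rng.choice(N_CHOICES))
        return alpha, k, hill_n, 1 if w > 0 else -1

    groups: list[RegulatorGroup] = []
    for t in range(n):
        regs = grn.regulators_of(t)
        if regs.size == 0:
            continue
        by_sign: dict[int, list[int]] = {1: [], -1: []}
        for reg in regs:
            by_sign[1 if grn.weights[t, reg] > 0 else -1].append(int(reg))
        for sign, members in by_sign.items():
            if not members:
                continue
            grouped = len(members) >= 2 and rng.random() < combo_probability
            if grouped:
                alphas, ks, ns = [], [], []
                for reg in members:
                    _, k, hill_n, _ = draw_edge(t, reg)
                    alphas.append(rng.uniform(*ALPHA_COMBO_MEMBER))
                    ks.append(k)
                    ns.append(hill_n)
                groups.append(
                    RegulatorGroup(
                        target=t,
                        regulators=members,
                        alpha=alphas,
                        k=ks,
                        n=ns,
                        sign=sign,
                        P=1,
                        alpha3=rng.uniform(*ALPHA_COMBO_GROUP),
                    )
                )
            else:
                for reg in members:
                    alpha, k, hill_n, s = draw_edge(t, reg)
                    groups.append(
                        RegulatorGroup(
                            target=t,
                            regulators=[reg],
                            alpha=[alpha],
                            k=[k],
                            n=[hill_n],
                            sign=s,
                        )
                    )

    return KineticParameters(
        genes=list(grn.genes),
        m=m,
        r=r,
        lambda_mrna=lam_m,
        lambda_prot=lam_p,
        groups=groups,
        metadata={"seed": seed, "combo_probability": combo_probability,
                  "median_abs_weight": median_w},
    )


def hill(y: float, k: float, n: float, alpha: float, sign: int = 1) -> float:
    """Single-regulator Hill term; output lies in [0, alpha].

    Activation (sign=+1): ``alpha * (y/k)^n / (1 + (y/k)^n)``;
    repression (sign=-1): ``alpha / (1 + (y/k)^n)``.
    """
    if np.any(np.asarray(y) < 0):
        raise KineticsError("regulator concentration must be non-negative")
    v = (np.asarray(y, dtype=float) / k) ** n
    if sign == 1:
        out = alpha * v / (1.0 + v)
    elif sign == -1:
        out = alpha / (1.0 + v)
    else:
        raise KineticsError(f"sign must be +1 or -1, got {sign}")
    return float(out) if np.isscalar(y) else out


def combined_regulation(y_values, group: RegulatorGroup) -> float:
    """Shared-denominator additive Hill value of one group, in activation form.

    For members with occupancies ``V_i = (y_i/k_i)^n_i``:

        (sum alpha_i V_i + alpha3 * P * prod V_i)
        / (1 + sum V_i + P * prod V_i)

    The size-one, P = 0 case reduces exactly to the single Hill term.
    The value is monotone in every y and bounded by max(alpha_i, alpha3).
    """
    y = np.asarray(y_values, dtype=float)
    if y.shape[0] != len(group.regulators):
        raise KineticsError(
            f"expected {len(group.regulators)} regulator concentrations, got {y.shape[0]}"
        )
    if np.any(y < 0):
        raise KineticsError("regulator concentration must be non-negative")
    v = (y / np.asarray(group.k)) ** np.asarray(group.n)
    num = float(np.dot(group.alpha, v))
    den = 1.0 + float(v.sum())
    if group.P == 1:
        prod = float(np.prod(v))
        num += group.alpha3 * prod
        den += prod
    return num / den


def regulation_input(y: np.ndarray, params: KineticParameters) -> np.ndarray:
    """Per-gene regulation factor f in [0, 1].

    Unregulated genes get f = 1 (basal transcription at the maximum
    rate).  Regulated genes average their group contributions: activator
    groups contribute their activation-form value; repressor groups
    contribute one minus it (unrepressed = full transcription).
    """
    n = params.n_genes
    f_sum = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    for g in params.groups:
        val = combined_regulation(y[g.regulators], g)
        contrib = val if g.sign == 1 else 1.0 - val
        f_sum[g.target] += contrib
        counts[g.target] += 1
    f = np.ones(n)
    reg = counts > 0
    f[reg] = f_sum[reg] / counts[reg]
    return np.clip(f, 0.0, 1.0)


def ode_rhs(
    state: np.ndarray,
    params: KineticParameters,
    effective_m: np.ndarray | None = None,
) -> np.ndarray:
    """Time derivative of the stacked state ``[x, y]``.

    `effective_m` replaces the per-gene maximum transcription rate (used
    by perturbations that scale m); defaults to ``params.m``.
    """
    n = params.n_genes
    state = np.asarray(state, dtype=float)
    if state.shape[0] != 2 * n:
        raise KineticsError(f"state must have length {2 * n}, got {state.shape[0]}")
    m = params.m if effective_m is None else np.asarray(effective_m, dtype=float)
    if m.shape[0] != n:
        raise KineticsError(f"effective_m must have length {n}")
    x = state[:n]
    y = np.maximum(state[n:], 0.0)  # guard tiny negative solver excursions
    f = regulation_input(y, params)
    dx = m * f - params.lambda_mrna * x
    dy = params.r * x - params.lambda_prot * state[n:]
    return np.concatenate([dx, dy])


def make_rhs(params: KineticParameters, effective_m: np.ndarray | None = None):
    """Compiled-closure RHS ``f(t, state)`` for scipy's solvers.

    Precomputes flat arrays for singleton groups (the overwhelmingly
    common case) so the per-call cost is a handful of vector operations;
    multi-member groups are evaluated in a short Python loop.
    """
    n = params.n_genes
    m = (params.m if effective_m is None else np.asarray(effective_m, dtype=float)).copy()
    lam_m = params.lambda_mrna
    lam_p = params.lambda_prot
    r = params.r

    singles = [g for g in params.groups if len(g.regulators) == 1 and g.P == 0]
    single_ids = {id(g) for g in singles}
    multis = [g for g in params.groups if id(g) not in single_ids]
    s_tgt = np.array([g.target for g in singles], dtype=int)
    s_reg = np.array([g.regulators[0] for g in singles], dtype=int)
    s_alpha = np.array([g.alpha[0] for g in singles])
    s_k = np.array([g.k[0] for g in singles])
    s_n = np.array([g.n[0] for g in singles], dtype=float)
    s_act = np.array([g.sign == 1 for g in singles])

    counts = np.zeros(n, dtype=int)
    for g in params.groups:
        counts[g.target] += 1
    regulated = counts > 0
    counts_safe = np.where(regulated, counts, 1)

    def rhs(t: float, state: np.ndarray) -> np.ndarray:
        x = state[:n]
        y = np.maximum(state[n:], 0.0)
        f_sum = np.zeros(n)
        if s_tgt.size:
            v = (y[s_reg] / s_k) ** s_n
            val = s_alpha * v / (1.0 + v)
            np.add.at(f_sum, s_tgt, np.where(s_act, val, 1.0 - val))
        for g in multis:
            val = combined_regulation(y[g.regulators], g)
            f_sum[g.target] += val if g.sign == 1 else 1.0 - val
        f = np.where(regulated, np.clip(f_sum / counts_safe, 0.0, 1.0), 1.0)
        return np.concatenate([m * f - lam_m * x, r * x - lam_p * state[n:]])

    return rhs
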