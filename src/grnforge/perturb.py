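"""Perturbation design matrices and their effect on transcription rates.

A perturbation scales a gene's maximum transcription rate:

    m_i = m_i_input * (1 + pert)

with ``pert`` in [-1, inf): -1 is a full knockout, -0.8 an 80%%
knockdown, 0 no perturbation, and positive values overexpression (no
upper cap; the regulation function stays bounded in [0, 1] regardless,
perturbation scales m, not f).

A design is an experiments x genes matrix of pert values.  Five schemes
are provided: single-gene (one experiment per gene), combinatory
(k genes at a time, balanced across genes), targeted (co-regulators of a
shared target perturbed together), all-genes (every gene nudged by a
small random amount), and specific (explicit gene sets).  Designs over
the same gene list can be merged row-wise.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import GRN

__all__ = [
    "PerturbationDesign",
    "DesignError",
    "apply_perturbation",
    "single_gene_design",
    "combinatory_design",
    "targeted_design",
    "all_genes_design",
    "specific_design",
    "merge_designs",
    "read_design",
    "write_design",
]

OVEREXPRESSION_WARN_LEVEL = 10.0


class DesignError(ValueError):
    """Invalid perturbation design or strength."""


@dataclass
class PerturbationDesign:
    """Experiments x genes matrix of perturbation strengths."""

    genes: list[str]
    matrix: np.ndarray
    scheme: str = "custom"
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != len(self.genes):
            raise DesignError(
                f"design has {self.matrix.shape[1]} columns for {len(self.genes)} genes"
            )
        if np.any(self.matrix < -1):
            raise DesignError("perturbation strengths below -1 are impossible "
                              "(they would imply a negative transcription rate)")
        if not self.labels:
            self.labels = [f"exp{i}" for i in range(self.matrix.shape[0])]
        if len(self.labels) != self.matrix.shape[0]:
            raise DesignError("one label per experiment required")

    @property
    def n_experiments(self) -> int:
        return self.matrix.shape[0]

    def perturbed_genes(self, row: int) -> list[str]:
        return [self.genes[j] for j in np.nonzero(self.matrix[row])[0]]


def apply_perturbation(m_input, pert):
    """Effective transcription rate ``m_input * (1 + pert)``.

    ``pert = -0.8`` gives an 80% reduction of the control rate;
    ``pert = -1`` a complete knockout.
    """
    pert = np.asarray(pert, dtype=float)
    if np.any(pert < -1):
        raise DesignError(f"perturbation strength {pert} below -1 is impossible")
    out = np.asarray(m_input, dtype=float) * (1.0 + pert)
    return float(out) if out.ndim == 0 else out


def _check_strength(strength: float) -> None:
    if strength < -1:
        raise DesignError(f"strength {strength} below -1")
    if strength == 0:
        raise DesignError("strength 0 would perturb nothing")
    if strength > OVEREXPRESSION_WARN_LEVEL:
        warnings.warn(
            f"overexpression strength {strength} is extreme; the model stays "
            "bounded but dynamics may be stiff",
            stacklevel=3,
        )


def single_gene_design(genes: list[str], strength: float = -0.8) -> PerturbationDesign:
    """One experiment per gene, perturbing exactly that gene."""
    _check_strength(strength)
    n = len(genes)
    return PerturbationDesign(
        genes=list(genes),
        matrix=strength * np.eye(n),
        scheme="single",
        labels=[f"pert_{g}" for g in genes],
    )


def _rows_from_sets(genes, sets, strength) -> PerturbationDesign:
    index = {g: i for i, g in enumerate(genes)}
    mat = np.zeros((len(sets), len(genes)))
    labels = []
    for i, s in enumerate(sets):
        for g in s:
            mat[i, index[g]] = strength[g] if isinstance(strength, dict) else strength
        labels.append("pert_" + "+".join(sorted(s)))
    return PerturbationDesign(genes=list(genes), matrix=mat, labels=labels)


def combinatory_design(
    genes: list[str],
    genes_per_experiment: int,
    n_experiments: int,
    strength: float = -0.8,
    seed: int | None = None,
) -> PerturbationDesign:
    """k genes perturbed per experiment, balanced across genes.

    Unique gene sets are drawn without replacement, preferring the genes
    perturbed least often so far, so each gene appears a roughly equal
    number of times across the design.
    """
    _check_strength(strength)
    n = len(genes)
    k = genes_per_experiment
    if not 2 <= k <= n:
        raise DesignError(f"genes per experiment must be in [2, {n}], got {k}")
    from math import comb

    if n_experiments > comb(n, k):
        raise DesignError(
            f"{n_experiments} experiments requested but only {comb(n, k)} "
            f"unique {k}-gene combinations exist"
        )
    rng = np.random.default_rng(seed)
    counts = np.zeros(n, dtype=int)
    chosen: list[tuple[int, ...]] = []
    seen: set[tuple[int, ...]] = set()
    while len(chosen) < n_experiments:
        # favour the least-perturbed genes: sample among the minimal counts
        # first, breaking ties randomly; fall back to pure rejection.
        order = np.lexsort((rng.random(n), counts))
        cand = tuple(sorted(order[:k].tolist()))
        if cand in seen:
            pool = rng.permutation(n)[:k]
            cand = tuple(sorted(pool.tolist()))
            if cand in seen:
                continue
        seen.add(cand)
        chosen.append(cand)
        for j in cand:
            counts[j] += 1
    sets = [{genes[j] for j in row} for row in chosen]
    design = _rows_from_sets(genes, sets, strength)
    design.scheme = "combinatory"
    return design


def targeted_design(
    grn: GRN,
    genes_per_experiment: int,
    n_experiments: int,
    strength: float = -0.8,
    seed: int | None = None,
) -> PerturbationDesign:
    """Perturb co-regulators: each experiment's genes share a target.

    Every emitted gene set is a subset of some target's regulator set.
    If no set of the requested size exists the scheme falls back to
    smaller sets, so as many unique experiments as possible are created.
    """
    _check_strength(strength)
    rng = np.random.default_rng(seed)
    regulator_sets = [
        frozenset(int(j) for j in grn.regulators_of(t)) for t in range(grn.n_genes)
    ]
    regulator_sets = [s for s in regulator_sets if len(s) >= 1]
    if not any(len(s) >= 2 for s in regulator_sets):
        warnings.warn("network has no co-regulated targets; using single-gene sets")
    max_size = min(genes_per_experiment, max(map(len, regulator_sets), default=0))
    if max_size == 0:
        raise DesignError("network has no regulators to target")
    picked: list[frozenset[int]] = []
    used: set[frozenset[int]] = set()
    # prefer the largest feasible set size; fall back to smaller sizes to
    # keep experiments unique once a size is exhausted
    for size in range(max_size, 0, -1):
        if len(picked) >= n_experiments:
            break
        candidates = {
            frozenset(c)
            for s in regulator_sets
            if len(s) >= size
            for c in itertools.combinations(sorted(s), size)
        } - used
        pool = sorted(candidates, key=sorted)
        take = min(n_experiments - len(picked), len(pool))
        if take:
            idx = rng.choice(len(pool), size=take, replace=False)
            picked.extend(pool[i] for i in idx)
            used.update(pool[i] for i in idx)
    sets = [{grn.genes[j] for j in s} for s in picked]
    design = _rows_from_sets(grn.genes, sets, strength)
    design.scheme = "targeted"
    return design


def all_genes_design(
    genes: list[str],
    n_experiments: int,
    max_strength: float = 0.3,
    seed: int | None = None,
) -> PerturbationDesign:
    """Every gene perturbed by a small random amount, either direction.

    Emulates global perturbations such as medium or temperature changes.
    Entries are uniform on [-max_strength, max_strength] excluding 0;
    rows may repeat by chance.
    """
    if not 0 < max_strength < 1:
        raise DesignError(f"max_strength must be in (0, 1), got {max_strength}")
    rng = np.random.default_rng(seed)
    n = len(genes)
    mat = rng.uniform(-max_strength, max_strength, size=(n_experiments, n))
    zero = mat == 0
    while np.any(zero):  # essentially never; keeps the contract exact
        mat[zero] = rng.uniform(-max_strength, max_strength, size=int(zero.sum()))
        zero = mat == 0
    return PerturbationDesign(
        genes=list(genes),
        matrix=mat,
        scheme="all_genes",
        labels=[f"global{i}" for i in range(n_experiments)],
    )


def specific_design(
    genes: list[str],
    experiment_list: list[set[str] | list[str]],
    strength: float | dict[str, float] = -0.8,
) -> PerturbationDesign:
    """One experiment per listed gene set; only listed genes are perturbed.

    `strength` may be a scalar applied to every perturbed gene or a
    per-gene map.
    """
    gene_set = set(genes)
    sets: list[set[str]] = []
    for entry in experiment_list:
        s = set(entry)
        if not s:
            raise DesignError("empty perturbation set in experiment list")
        unknown = s - gene_set
        if unknown:
            raise DesignError(f"unknown gene(s) {sorted(unknown)} in experiment list")
        sets.append(s)
    if isinstance(strength, dict):
        for g, v in strength.items():
            if v < -1:
                raise DesignError(f"strength {v} for {g} below -1")
    else:
        _check_strength(strength)
    design = _rows_from_sets(genes, sets, strength)
    design.scheme = "specific"
    return design


def merge_designs(designs: list[PerturbationDesign]) -> PerturbationDesign:
    """Concatenate designs row-wise, dropping duplicate rows (first kept)."""
    if not designs:
        raise DesignError("nothing to merge")
    genes = designs[0].genes
    for d in designs[1:]:
        if d.genes != genes:
            raise DesignError("designs cover different gene lists and cannot be merged")
    rows, labels, seen = [], [], set()
    for d in designs:
        for i in range(d.n_experiments):
            key = d.matrix[i].tobytes()
            if key in seen:
                continue
            seen.add(key)
            rows.append(d.matrix[i])
            labels.append(d.labels[i])
    return PerturbationDesign(
        genes=list(genes),
        matrix=np.vstack(rows),
        scheme="+".join(dict.fromkeys(d.scheme for d in designs)),
        labels=labels,
    )


def write_design(design: PerturbationDesign, path) -> None:
    """TSV with experiments as rows, genes as columns."""
    pd.DataFrame(design.matrix, index=design.labels, columns=design.genes).to_csv(
        path, sep="\t"
    )


def read_design(path) -> PerturbationDesign:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PerturbationDesign(
        genes=[str(c) for c in df.columns],
        matrix=df.to_numpy(dtype=float),
        labels=[str(i) for i in df.index],
    )
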