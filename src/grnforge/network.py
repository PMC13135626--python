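"""Gene regulatory network container, generation, motif census and I/O.

A GRN is a directed, signed, weighted graph of regulator->target
transcriptional influences.  The adjacency matrix is oriented
``W[target, regulator]``: row *i* collects the regulators of gene *i*,
so the ODE right-hand side of gene *i* reads straight off row *i*.
A nonzero entry means the column gene regulates the row gene; positive
weights are activations, negative weights repressions.

Networks are generated by a motif-aware preferential-attachment growth
process: nodes attach to existing nodes with probability proportional to
``(degree + 1) ** gamma`` (a power-law kernel, producing hubs and a
heavy-tailed degree distribution), and a tunable fraction of attachments
is completed into feed-forward loops (FFLs), the three-node motif
X->Y, X->Z, Y->Z that is enriched in biological networks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GRN",
    "MotifCensus",
    "GRNError",
    "generate_network",
    "assign_edge_weights",
    "count_motifs",
    "read_network",
    "write_network",
    "topology_summary",
]


class GRNError(ValueError):
    """Invalid network structure or generation parameters."""


@dataclass
class GRN:
    """A signed, weighted gene regulatory network.

    Parameters
    ----------
    genes : list of str
        Unique gene identifiers, fixing row/column order of `weights`.
    weights : ndarray of shape (n_genes, n_genes)
        Signed edge weights, oriented ``weights[target, regulator]``.
        A nonzero entry means regulator -> target.
    metadata : dict
        Generator provenance (seed, parameters) or import provenance.
    """

    genes: list[str]
    weights: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise GRNError(f"weight matrix must be square, got {self.weights.shape}")
        if len(self.genes) != self.weights.shape[0]:
            raise GRNError(
                f"{len(self.genes)} genes but weight matrix of "
                f"dimension {self.weights.shape[0]}"
            )
        if len(set(self.genes)) != len(self.genes):
            raise GRNError("gene identifiers must be unique")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.weights))

    def edges(self) -> list[tuple[int, int]]:
        """(target_index, regulator_index) pairs of all edges."""
        t, r = np.nonzero(self.weights)
        return list(zip(t.tolist(), r.tolist()))

    def regulators_of(self, target: int) -> np.ndarray:
        """Column indices of the regulators of gene `target`."""
        return np.nonzero(self.weights[target])[0]

    def to_networkx(self) -> nx.DiGraph:
        """Directed graph with a ``weight`` attribute per edge."""
        g = nx.DiGraph()
        g.add_nodes_from(self.genes)
        for t, r in self.edges():
            g.add_edge(self.genes[r], self.genes[t], weight=self.weights[t, r])
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph, default_weight: float = 1.0) -> "GRN":
        genes = list(g.nodes())
        idx = {name: i for i, name in enumerate(genes)}
        w = np.zeros((len(genes), len(genes)))
        for u, v, data in g.edges(data=True):
            w[idx[v], idx[u]] = data.get("weight", default_weight)
        return cls(genes=genes, weights=w, metadata={"source": "networkx"})


@dataclass
class MotifCensus:
    """Counts of classified three-node motifs over unordered gene triads.

    Counted on the unsigned directed graph; a triad is classified only if
    its induced subgraph is exactly the motif:

    - ``ffl``     : X->Y, X->Z, Y->Z (feed-forward loop, any labelling)
    - ``cycle``   : X->Y->Z->X (3-cycle)
    - ``cascade`` : X->Y->Z only (2-edge chain)
    - ``uplink``  : X->Z, Y->Z only (fan-in: two regulators, one target)
    - ``downlink``: X->Y, X->Z only (fan-out: one regulator, two targets)
    """

    ffl: int = 0
    cascade: int = 0
    uplink: int = 0
    downlink: int = 0
    cycle: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "ffl": self.ffl,
            "cascade": self.cascade,
            "uplink": self.uplink,
            "downlink": self.downlink,
            "cycle": self.cycle,
        }


def _default_gene_names(n: int) -> list[str]:
    width = len(str(n - 1)) if n > 1 else 1
    return [f"G{str(i).zfill(width)}" for i in range(n)]


def generate_network(
    n_genes: int,
    sparsity: float,
    ffl_weight: float = 0.5,
    seed: int | None = None,
    gamma: float = 1.0,
    weight_low: float = 0.1,
    weight_high: float = 1.0,
    activation_fraction: float = 0.7,
) -> GRN:
    """Grow an FFL-enriched scale-free GRN by preferential attachment.

    Parameters
    ----------
    n_genes : int
        Number of genes (>= 3).
    sparsity : float
        Target mean number of links per node; the realized edge count is
        ``round(sparsity * n_genes)`` up to attachment feasibility.
    ffl_weight : float in [0, 1]
        Probability that an attachment event is completed into a
        feed-forward loop by adding the closing edge of an open 2-path.
    seed : int, optional
        Seed for the generator; same seed and parameters give a
        bit-identical network.
    gamma : float
        Exponent of the power-law attachment kernel
        ``p(u) ∝ (degree(u) + 1) ** gamma``.

    Returns
    -------
    GRN
        Weakly connected, with no self-loops and signed weights drawn by
        :func:`assign_edge_weights`.
    """
    if n_genes < 3:
        raise GRNError(f"need at least 3 genes, got {n_genes}")
    target_edges = int(round(sparsity * n_genes))
    if sparsity <= 0 or target_edges > n_genes * (n_genes - 1):
        raise GRNError(
            f"infeasible density: {sparsity} links/node requested for "
            f"{n_genes} genes (max {n_genes - 1})"
        )
    rng = np.random.default_rng(seed)
    adj = np.zeros((n_genes, n_genes), dtype=bool)  # adj[t, r]: r -> t

    def add_edge(r: int, t: int) -> bool:
        if r == t or adj[t, r]:
            return False
        adj[t, r] = True
        return True

    def degree(active: int) -> np.ndarray:
        sub = adj[:active, :active]
        return sub.sum(axis=0) + sub.sum(axis=1)

    def pick(active: int, exclude: int) -> int:
        w = (degree(active).astype(float) + 1.0) ** gamma
        if exclude < active:
            w[exclude] = 0.0
        return int(rng.choice(active, p=w / w.sum()))

    def close_ffl(v: int, active: int) -> bool:
        # v already has edges; find an open 2-path through v and close it
        # into an FFL.  Any of the three FFL roles may involve v.
        regs_v = np.nonzero(adj[v, :active])[0]  # u -> v
        tgts_v = np.nonzero(adj[:active, v])[0]  # v -> u
        candidates: list[tuple[int, int]] = []
        for u in regs_v:  # u -> v; w -> u gives w->u, u->v, close w->v
            for w in np.nonzero(adj[u, :active])[0]:
                if w != v and not adj[v, w]:
                    candidates.append((int(w), v))
        for u in tgts_v:  # v -> u; u -> w gives v->u, u->w, close v->w
            for w in np.nonzero(adj[:active, u])[0]:
                if w != v and not adj[w, v]:
                    candidates.append((v, int(w)))
        for u in regs_v:  # u -> v; v -> w gives the cascade u->v->w, close u->w
            for w in tgts_v:
                if w != u and not adj[w, u]:
                    candidates.append((int(u), int(w)))
        if not candidates:
            return False
        r, t = candidates[rng.integers(len(candidates))]
        return add_edge(r, t)

    # seed triad: a chain keeps all three nodes in one weak component
    add_edge(0, 1)
    add_edge(1, 2)
    edges_left = target_edges - 2

    # growth: each new node attaches to the existing component
    for v in range(3, n_genes):
        remaining_nodes = n_genes - v
        budget = max(1, int(round(edges_left / remaining_nodes)))
        u = pick(v, exclude=v)
        if rng.random() < 0.5:
            add_edge(u, v)
        else:
            add_edge(v, u)
        edges_left -= 1
        for _ in range(budget - 1):
            if edges_left <= 0:
                break
            made = False
            if rng.random() < ffl_weight:
                made = close_ffl(v, v + 1)
            if not made:
                u = pick(v + 1, exclude=v)
                made = add_edge(u, v) if rng.random() < 0.5 else add_edge(v, u)
            if made:
                edges_left -= 1

    # top-up to the target count on the full node set
    attempts = 0
    while edges_left > 0 and attempts < 50 * target_edges:
        attempts += 1
        made = False
        if rng.random() < ffl_weight:
            v = int(rng.integers(n_genes))
            made = close_ffl(v, n_genes)
        if not made:
            r = int(rng.integers(n_genes))
            t = int(rng.integers(n_genes))
            made = add_edge(r, t)
        if made:
            edges_left -= 1

    grn = GRN(
        genes=_default_gene_names(n_genes),
        weights=adj.astype(float),
        metadata={
            "generator": "grnforge.preferential_attachment",
            "seed": seed,
            "n_genes": n_genes,
            "sparsity": sparsity,
            "ffl_weight": ffl_weight,
            "gamma": gamma,
        },
    )
    return assign_edge_weights(
        grn,
        weight_low,
        weight_high,
        activation_fraction,
        seed=int(rng.integers(2**31)),
    )


def assign_edge_weights(
    grn: GRN,
    weight_low: float = 0.1,
    weight_high: float = 1.0,
    activation_fraction: float = 0.7,
    seed: int | None = None,
) -> GRN:
    """Draw signed weights for every existing edge; topology unchanged.

    Magnitudes are Uniform[weight_low, weight_high]; the sign is positive
    (activation) with probability `activation_fraction`.  The spread makes
    the strong/weak interaction classes of the kinetic-parameter
    assignment (median split on |weight|) non-degenerate.
    """
    if weight_low > weight_high:
        raise GRNError("weight_low must not exceed weight_high")
    edges = grn.edges()
    if not edges:
        raise GRNError("network has no edges to weight")
    rng = np.random.default_rng(seed)
    w = np.zeros_like(grn.weights)
    for t, r in edges:
        mag = rng.uniform(weight_low, weight_high)
        sign = 1.0 if rng.random() < activation_fraction else -1.0
        w[t, r] = sign * mag
    meta = dict(grn.metadata)
    meta["weight_seed"] = seed
    return GRN(genes=list(grn.genes), weights=w, metadata=meta)


_TWO_EDGE_MOTIFS = {
    # keys: frozenset of directed edges within the triad, nodes relabelled
    # by enumeration order a<b<c is not stable, so classify structurally.
}


def _classify_triad(edges: set[tuple[int, int]], nodes: tuple[int, int, int]) -> str | None:
    """Classify the induced triad given its directed edge set."""
    n_edges = len(edges)
    if n_edges == 3:
        outdeg = {v: 0 for v in nodes}
        indeg = {v: 0 for v in nodes}
        for r, t in edges:
            outdeg[r] += 1
            indeg[t] += 1
        # mutual edges (u->v and v->u) disqualify both patterns
        if any((t, r) in edges for r, t in edges):
            return None
        if sorted(outdeg.values()) == [0, 1, 2]:
            return "ffl"
        if sorted(outdeg.values()) == [1, 1, 1]:
            return "cycle"
        return None
    if n_edges == 2:
        (r1, t1), (r2, t2) = edges
        if {t1, t2} == {r1, r2} and (r1, t1) == (t2, r2):
            return None  # mutual pair
        if t1 == t2:
            return "uplink"
        if r1 == r2:
            return "downlink"
        if t1 == r2 or t2 == r1:
            return "cascade"
        return None
    return None


def count_motifs(grn: GRN) -> MotifCensus:
    """Exhaustively census three-node motifs on the unsigned digraph.

    Every unordered gene triad is inspected and classified by its induced
    subgraph; triads whose subgraph is not exactly one of the five
    patterns (e.g. containing mutual edges or more edges than the motif)
    are left unclassified.
    """
    adj = grn.weights != 0
    n = grn.n_genes
    census = MotifCensus()
    # restrict enumeration to connected triads via adjacency lists
    neighbors: list[set[int]] = []
    for i in range(n):
        nb = set(np.nonzero(adj[i])[0].tolist()) | set(np.nonzero(adj[:, i])[0].tolist())
        nb.discard(i)
        neighbors.append(nb)
    seen: set[tuple[int, int, int]] = set()
    for a in range(n):
        for b in neighbors[a]:
            third = (neighbors[a] | neighbors[b]) - {a, b}
            for c in third:
                key = tuple(sorted((a, int(b), int(c))))
                if key in seen:
                    continue
                seen.add(key)
                i, j, k = key
                edges = {
                    (r, t)
                    for r, t in itertools.permutations((i, j, k), 2)
                    if adj[t, r]
                }
                kind = _classify_triad(edges, key)
                if kind is not None:
                    setattr(census, kind, getattr(census, kind) + 1)
    return census


def _sniff_sep(path: str) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_network(path, format: str = "edge-list", genes: list[str] | None = None) -> GRN:
    """Read a GRN from an edge list or adjacency matrix file.

    Edge-list files have three columns (regulator, target, weight),
    tab- or comma-separated, with an optional header.  Adjacency files
    are square numeric matrices with gene names as header row and first
    column.  Orientation on disk is regulator->target; in memory the
    matrix is stored ``W[target, regulator]``.

    Parameters
    ----------
    genes : list of str, optional
        Declared gene universe for edge lists; edges naming genes outside
        it raise an error.  Without it the gene set is inferred from the
        file in order of first appearance.
    """
    path = str(path)
    if format == "adjacency":
        df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0,
                         float_precision="round_trip")
        if df.shape[0] != df.shape[1]:
            raise GRNError(f"adjacency matrix is not square: {df.shape}")
        mat = df.to_numpy(dtype=float)  # rows = regulators on disk
        return GRN(
            genes=[str(g) for g in df.index],
            weights=mat.T.copy(),
            metadata={"source": path, "format": "adjacency"},
        )
    if format != "edge-list":
        raise GRNError(f"unknown network format {format!r}")
    if genes is None:
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#genes:"):
            sep = _sniff_sep(path)
            genes = [g for g in first[len("#genes:"):].strip().split(sep) if g]
    df = pd.read_csv(path, sep=_sniff_sep(path), header=None, comment="#",
                     float_precision="round_trip")
    # tolerate a header row of non-numeric weight
    try:
        float(df.iloc[0, 2])
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] < 3:
        raise GRNError("edge list needs three columns: regulator, target, weight")
    regs = df.iloc[:, 0].astype(str).tolist()
    tgts = df.iloc[:, 1].astype(str).tolist()
    try:
        ws = df.iloc[:, 2].astype(float).tolist()
    except ValueError as exc:
        raise GRNError(f"non-numeric edge weight in {path}: {exc}") from exc
    if genes is None:
        ordered: list[str] = []
        for g in itertools.chain(regs, tgts):
            if g not in ordered:
                ordered.append(g)
        genes = ordered
    index = {g: i for i, g in enumerate(genes)}
    w = np.zeros((len(genes), len(genes)))
    for r, t, weight in zip(regs, tgts, ws):
        if r not in index or t not in index:
            missing = r if r not in index else t
            raise GRNError(f"edge references unknown gene {missing!r}")
        w[index[t], index[r]] = weight
    return GRN(genes=list(genes), weights=w, metadata={"source": path, "format": "edge-list"})


def write_network(grn: GRN, path, format: str = "edge-list") -> None:
    """Write a GRN as an edge list (TSV) or adjacency matrix (CSV).

    Round-trips through :func:`read_network` exactly (identifiers, full
    floating-point weights, orientation).
    """
    path = str(path)
    if format == "adjacency":
        # rows = regulators on disk (regulator -> target reads left to right)
        df = pd.DataFrame(grn.weights.T, index=grn.genes, columns=grn.genes)
        df.to_csv(path, float_format=None)
        return
    if format != "edge-list":
        raise GRNError(f"unknown network format {format!r}")
    with open(path, "w") as fh:
        # comment line pinning the gene universe and order, so isolated
        # genes and ordering survive the round trip
        fh.write("#genes:\t" + "\t".join(grn.genes) + "\n")
        fh.write("regulator\ttarget\tweight\n")
        for t, r in grn.edges():
            fh.write(f"{grn.genes[r]}\t{grn.genes[t]}\t{float(grn.weights[t, r])!r}\n")


def topology_summary(grn: GRN) -> dict:
    """Basic topology report: size, sparsity, degree structure."""
    adj = grn.weights != 0
    in_deg = adj.sum(axis=1)  # regulators per target (row sums)
    out_deg = adj.sum(axis=0)  # targets per regulator (column sums)
    n_edges = int(adj.sum())
    return {
        "n_genes": grn.n_genes,
        "n_edges": n_edges,
        "mean_links_per_node": n_edges / grn.n_genes if grn.n_genes else 0.0,
        "in_degree": in_deg.astype(int).tolist(),
        "out_degree": out_deg.astype(int).tolist(),
        "max_out_degree": int(out_deg.max()) if grn.n_genes else 0,
        "n_activating": int((grn.weights > 0).sum()),
        "n_repressing": int((grn.weights < 0).sum()),
    }
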