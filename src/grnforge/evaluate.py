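"""Benchmarking of predicted networks and exploratory data metrics.

A prediction — a dense score matrix (oriented ``S[target, regulator]``
like the truth) or a ranked edge list — is swept against the ground
truth's nonzero entries to build ROC and PR curves.  Tied scores are
traversed as a single block, which draws a straight segment through the
tied region and makes the result independent of within-tie order.

Predictions that rank only part of the candidate edge set are
*extended*: the ROC curve by a straight line to (1, 1), the PR curve by
assuming the remaining positives are spread uniformly among the
remaining candidates — both are exactly what randomly guessing the rest
of the network would achieve, so extended areas remain comparable across
methods.  Methods that never score self-loops can be compared fairly by
dropping diagonal candidates from both prediction and truth.

The module also provides the exploratory data-property report used to
compare simulated with real perturbation data (fraction of unique
values, replicate and dataset correlations, perturbation rank, condition
number and singular-value spectrum) and a minimal Z-score inference
baseline so the benchmark has an end-to-end consumer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import GRN

__all__ = [
    "BenchmarkResult",
    "EDAReport",
    "BenchmarkError",
    "benchmark",
    "auc",
    "eda",
    "zscore_baseline",
]


class BenchmarkError(ValueError):
    """Invalid benchmarking input."""


@dataclass
class BenchmarkResult:
    """ROC/PR curves (with any extension) and their areas."""

    roc: np.ndarray  # (points, 2): FPR, TPR
    pr: np.ndarray  # (points, 2): recall, precision
    auroc: float
    aupr: float
    n_candidates: int
    n_positives: int
    extended: bool
    extra: dict = field(default_factory=dict)

    def summary(self) -> str:
        ext = " (extended)" if self.extended else ""
        return (
            f"AUROC {self.auroc:.4f}, AUPR {self.aupr:.4f} over "
            f"{self.n_candidates} candidate edges, {self.n_positives} true{ext}"
        )


@dataclass
class EDAReport:
    """Data-property metrics of a fold-change matrix."""

    fraction_unique: float
    median_replicate_corr: float | None
    median_dataset_corr: float
    perturbation_rank: float | None
    log10_condition_number: float | None
    singular_values: np.ndarray

    def as_dict(self) -> dict:
        return {
            "fraction_unique": self.fraction_unique,
            "median_replicate_corr": self.median_replicate_corr,
            "median_dataset_corr": self.median_dataset_corr,
            "perturbation_rank": self.perturbation_rank,
            "log10_condition_number": self.log10_condition_number,
        }


def auc(points) -> float:
    """Trapezoidal area under a curve given as (x, y) points.

    x must be non-decreasing; fewer than two points is degenerate.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise BenchmarkError("need at least two curve points")
    x, y = pts[:, 0], pts[:, 1]
    if np.any(np.diff(x) < -1e-12):
        raise BenchmarkError("curve x-coordinates must be non-decreasing")
    return float(np.trapezoid(y, x))


def _scores_from_prediction(predicted, genes: list[str], n: int) -> np.ndarray:
    """Dense score matrix S[target, regulator] with NaN = unscored."""
    if isinstance(predicted, pd.DataFrame):
        predicted = predicted.to_numpy()
    if isinstance(predicted, np.ndarray):
        if predicted.shape != (n, n):
            raise BenchmarkError(
                f"score matrix shape {predicted.shape} does not match truth ({n}, {n})"
            )
        return predicted.astype(float)
    # ranked edge list: iterable of (regulator, target, score)
    index = {g: i for i, g in enumerate(genes)}
    scores = np.full((n, n), np.nan)
    for reg, tgt, sc in predicted:
        if reg not in index or tgt not in index:
            missing = reg if reg not in index else tgt
            raise BenchmarkError(f"prediction references unknown gene {missing!r}")
        scores[index[tgt], index[reg]] = float(sc)
    return scores


def benchmark(
    predicted,
    truth: GRN,
    include_self_loops: bool = True,
    signed: bool = False,
) -> BenchmarkResult:
    """Score a predicted network against the ground truth.

    Parameters
    ----------
    predicted : ndarray, DataFrame or iterable of (regulator, target, score)
        Dense matrices use the truth's orientation ``[target, regulator]``
        with NaN marking unscored candidates; edge lists score the listed
        candidates only.  Candidates are ranked by descending |score|.
    truth : GRN
        Nonzero weight entries are the positive edges.
    include_self_loops : bool
        When False, diagonal candidates are removed from both the
        prediction and the truth before sweeping.
    signed : bool
        When True a predicted edge only counts as a true positive if its
        score's sign matches the truth weight's sign.
    """
    n = truth.n_genes
    scores = _scores_from_prediction(predicted, truth.genes, n)
    candidate = np.ones((n, n), dtype=bool)
    if not include_self_loops:
        np.fill_diagonal(candidate, False)
    truth_edge = (truth.weights != 0) & candidate
    n_pos = int(truth_edge.sum())
    n_cand = int(candidate.sum())
    if n_pos == 0:
        raise BenchmarkError("truth network has no positive edges; metrics undefined")

    scored = candidate & ~np.isnan(scores)
    sc = np.abs(scores[scored])
    if signed:
        hit = truth_edge[scored] & (np.sign(scores[scored]) == np.sign(truth.weights[scored]))
    else:
        hit = truth_edge[scored]

    order = np.argsort(-sc, kind="stable")
    sc_sorted = sc[order]
    hit_sorted = hit[order]

    # cumulative counts at tie-block boundaries
    tp_pts, k_pts = [0], [0]
    i = 0
    m = sc_sorted.size
    tp = 0
    while i < m:
        j = i
        while j < m and sc_sorted[j] == sc_sorted[i]:
            j += 1
        tp += int(hit_sorted[i:j].sum())
        tp_pts.append(tp)
        k_pts.append(j)
        i = j
    tp_arr = np.asarray(tp_pts, dtype=float)
    k_arr = np.asarray(k_pts, dtype=float)
    fp_arr = k_arr - tp_arr

    n_scored = m
    tp_last = tp_arr[-1]
    extended = n_scored < n_cand

    # ROC: rates over all positives/negatives of the candidate set
    n_neg = n_cand - n_pos
    fpr = fp_arr / n_neg if n_neg else np.zeros_like(fp_arr)
    tpr = tp_arr / n_pos
    roc = np.column_stack([fpr, tpr])
    if extended:
        roc = np.vstack([roc, [1.0, 1.0]])  # linear random-guess extension

    # PR: precision TP/k at each boundary; anchor recall 0 at the first
    # block's precision
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(k_arr > 0, tp_arr / np.maximum(k_arr, 1), np.nan)
    rec = tp_arr / n_pos
    pr_pts = [(rec[j], prec[j]) for j in range(1, len(k_arr))]
    if extended:
        t_rem = n_pos - tp_last
        c_rem = n_cand - n_scored
        if t_rem > 0:
            # remaining positives uniform among remaining candidates: each
            # recovered positive advances the rank by c_rem / t_rem
            step = c_rem / t_rem
            for j in range(1, int(t_rem) + 1):
                tp_j = tp_last + j
                pr_pts.append((tp_j / n_pos, tp_j / (n_scored + j * step)))
    if not pr_pts:  # no scored candidates and no positives left unreachable
        pr_pts = [(1.0, n_pos / n_cand)]
    first_prec = pr_pts[0][1]
    pr = np.vstack([[0.0, first_prec], np.asarray(pr_pts, dtype=float)])

    return BenchmarkResult(
        roc=roc,
        pr=pr,
        auroc=auc(roc),
        aupr=auc(pr),
        n_candidates=n_cand,
        n_positives=n_pos,
        extended=bool(extended),
        extra={"n_scored": int(n_scored), "signed": signed},
    )


def plot_curves(result: BenchmarkResult, path=None, ax=None):
    """Plot the ROC and PR curves side by side (PNG/SVG via `path`)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        fig, (ax_roc, ax_pr) = plt.subplots(1, 2, figsize=(8, 3.5))
    else:
        ax_roc, ax_pr = ax
        fig = ax_roc.figure
    ax_roc.plot(result.roc[:, 0], result.roc[:, 1], lw=1.5)
    ax_roc.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax_roc.set(xlabel="FPR", ylabel="TPR", title=f"ROC (AUROC {result.auroc:.3f})")
    ax_pr.plot(result.pr[:, 0], result.pr[:, 1], lw=1.5)
    base = result.n_positives / result.n_candidates
    ax_pr.axhline(base, ls="--", c="grey", lw=0.8)
    ax_pr.set(xlabel="recall", ylabel="precision", title=f"PR (AUPR {result.aupr:.3f})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def _round_sig(x: np.ndarray, digits: int = 6) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mag = np.floor(np.log10(np.abs(x), where=x != 0, out=np.zeros_like(x)))
    factor = 10.0 ** (digits - 1 - mag)
    return np.where(x == 0, 0.0, np.round(x * factor) / factor)


def eda(fold_change, design_matrix) -> EDAReport:
    """Exploratory data-property report of a fold-change matrix.

    Parameters
    ----------
    fold_change : ndarray (rows x genes)
        One row per experiment (replicates expanded), aligned with
        `design_matrix`'s rows.
    design_matrix : ndarray (rows x genes)
        Perturbation strengths; identical rows identify replicates, rows
        with exactly one nonzero entry identify single-gene knockdowns
        for the perturbation-rank metric.

    Notes
    -----
    - Values are compared at 6 significant digits when counting unique
      entries.
    - Perturbation rank of an experiment is the fractional rank of its
      targeted gene when genes are ordered by fold change ascending
      (most knocked down first); 1/n_genes means the target was the most
      knocked-down gene.  The median over single-knockdown experiments is
      reported, None if there are none.
    """
    fc = np.asarray(fold_change, dtype=float)
    design = np.asarray(design_matrix, dtype=float)
    if fc.shape != design.shape:
        raise BenchmarkError(
            f"fold-change shape {fc.shape} does not match design {design.shape}"
        )
    n_rows, n_genes = fc.shape

    uniq = np.unique(_round_sig(fc.ravel()))
    fraction_unique = uniq.size / fc.size

    # replicate pairs: identical design rows
    groups: dict[bytes, list[int]] = {}
    for i in range(n_rows):
        groups.setdefault(design[i].tobytes(), []).append(i)
    rep_corrs = []
    for rows in groups.values():
        for a in range(len(rows)):
            for b in range(a + 1, len(rows)):
                rep_corrs.append(_pearson(fc[rows[a]], fc[rows[b]]))
    median_rep = float(np.median(rep_corrs)) if rep_corrs else None

    all_corrs = [
        _pearson(fc[a], fc[b]) for a in range(n_rows) for b in range(a + 1, n_rows)
    ]
    median_all = float(np.median(all_corrs)) if all_corrs else float("nan")

    ranks = []
    for i in range(n_rows):
        nz = np.nonzero(design[i])[0]
        if nz.size == 1 and design[i, nz[0]] < 0:
            target = nz[0]
            rank = 1 + int(np.sum(fc[i] < fc[i, target]))
            ranks.append(rank / n_genes)
    pert_rank = float(np.median(ranks)) if ranks else None

    sv = np.linalg.svd(fc, compute_uv=False)
    if sv.size and sv[-1] > 0:
        log_cond = float(np.log10(sv[0] / sv[-1]))
    else:
        log_cond = None

    return EDAReport(
        fraction_unique=fraction_unique,
        median_replicate_corr=median_rep,
        median_dataset_corr=median_all,
        perturbation_rank=pert_rank,
        log10_condition_number=log_cond,
        singular_values=sv,
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def zscore_baseline(fold_change, design_matrix) -> np.ndarray:
    """Z-score network inference from single-gene perturbation data.

    Fold changes are standardized per gene (column) across experiments;
    the score of edge regulator -> target is the mean |z| of the target
    in the experiments that perturb exactly that regulator.  Regulators
    never singly perturbed leave their column NaN (unscored), which the
    benchmark treats as missing and covers by curve extension.

    Returns a score matrix ``S[target, regulator]``.
    """
    fc = np.asarray(fold_change, dtype=float)
    design = np.asarray(design_matrix, dtype=float)
    if fc.shape != design.shape:
        raise BenchmarkError(
            f"fold-change shape {fc.shape} does not match design {design.shape}"
        )
    n_rows, n_genes = fc.shape
    mu = fc.mean(axis=0)
    sd = fc.std(axis=0)
    sd[sd == 0] = 1.0
    z = (fc - mu) / sd

    scores = np.full((n_genes, n_genes), np.nan)
    for g in range(n_genes):
        rows = [
            i
            for i in range(n_rows)
            if design[i, g] != 0 and np.count_nonzero(design[i]) == 1
        ]
        if rows:
            scores[:, g] = np.abs(z[rows]).mean(axis=0)
    return scores
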