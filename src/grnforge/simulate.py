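"""Experiment simulation: steady states, time series and dataset assembly.

Every simulation starts from the control: the unperturbed system is
integrated from a random non-negative start until a steady state is
found (the change in every mRNA and protein falls below a tolerance,
default 1e-5, on two consecutive accepted solver steps) or a step budget
(default 10 000) is exhausted.  Each experiment then applies its
perturbation row to the transcription rates and re-integrates from the
control state, either to a new steady state (single endpoint) or over a
fixed time span with linearly or logarithmically spaced output points.
Systems that never settle — sustained oscillations from feedback
cycles — report ``converged=False`` and fall back to the last computed
state.

Integration uses the stiffness-switching LSODA method with absolute and
relative tolerances of 1e-8.  The ODE itself is deterministic; replicate
variation comes entirely from the noise model applied afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import LSODA, solve_ivp
from scipy.optimize import root

from .kinetics import KineticParameters, make_rhs
from .noise import NoiseConfig, apply_noise
from .perturb import PerturbationDesign, apply_perturbation

__all__ = [
    "ExpressionDataset",
    "SimulationError",
    "find_steady_state",
    "simulate_experiment",
    "run_design",
    "to_fold_change",
]

STEADY_TOL = 1e-5
MAX_STEPS = 10_000
SOLVER_TOL = 1e-8
DEFAULT_T_SPAN = (0.0, 50.0)
DEFAULT_N_TIMEPOINTS = 10


class SimulationError(RuntimeError):
    """Numerical failure during integration."""


@dataclass
class ExpressionDataset:
    """Simulated expression values for a perturbation design.

    ``values`` is (experiments*replicates) x genes for steady-state data
    or (experiments*replicates) x genes x timepoints for time series.
    ``noise_applied`` holds the realized noise factors (multiplicative
    models) or addends, all-ones/all-zeros when no noise was requested.
    """

    genes: list[str]
    values: np.ndarray
    control: np.ndarray
    protein_values: np.ndarray | None = None
    timepoints: np.ndarray | None = None
    replicates: np.ndarray | None = None
    experiment: np.ndarray | None = None
    labels: list[str] = field(default_factory=list)
    noise_applied: np.ndarray | None = None
    converged: np.ndarray | None = None
    clean_values: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Steady-state values as genes x experiments (TSV-ready)."""
        if self.values.ndim != 2:
            raise SimulationError("to_frame supports steady-state datasets; "
                                  "use to_long_frame for time series")
        return pd.DataFrame(self.values.T, index=self.genes, columns=self.labels)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: experiment, replicate, gene, time, value."""
        if self.values.ndim == 2:
            df = self.to_frame().reset_index(names="gene").melt(
                id_vars="gene", var_name="experiment", value_name="value"
            )
            return df
        rows = []
        for i in range(self.n_rows):
            for ti, t in enumerate(self.timepoints):
                for gi, g in enumerate(self.genes):
                    rows.append((self.labels[i], g, t, self.values[i, gi, ti]))
        return pd.DataFrame(rows, columns=["experiment", "gene", "time", "value"])


def _integrate_to_steady(
    rhs,
    init: np.ndarray,
    tol: float = STEADY_TOL,
    max_steps: int = MAX_STEPS,
    detector: str = "residual",
) -> tuple[np.ndarray, bool, float]:
    """Step LSODA until the steady-state test passes twice in a row.

    Returns (state, converged, final_time).  The canonical "residual"
    detector is the multidimensional root check — the system is steady
    when no mRNA or protein derivative exceeds the tolerance.  The
    "movement" variant instead requires that no species has moved more
    than the tolerance over an accepted step.
    """
    if detector not in ("residual", "movement"):
        raise ValueError(f"detector must be 'residual' or 'movement', got {detector!r}")
    init = np.asarray(init, dtype=float)
    if np.max(np.abs(rhs(0.0, init))) < tol:  # already steady
        return _polish_root(rhs, init), True, 0.0
    solver = LSODA(rhs, 0.0, init, t_bound=np.inf,
                   rtol=SOLVER_TOL, atol=SOLVER_TOL)
    quiet = 0
    prev = init
    for _ in range(max_steps):
        msg = solver.step()
        if solver.status == "failed":
            raise SimulationError(f"ODE solver failed: {msg}")
        state = solver.y
        if not np.all(np.isfinite(state)):
            bad = int(np.nonzero(~np.isfinite(state))[0][0])
            raise SimulationError(
                f"non-finite state during integration (component {bad})"
            )
        if detector == "residual":
            settled = np.max(np.abs(rhs(solver.t, state))) < tol
        else:
            settled = np.max(np.abs(state - prev)) < tol
        prev = state
        if settled:
            quiet += 1
            if quiet >= 2:
                return _polish_root(rhs, state), True, solver.t
        else:
            quiet = 0
    return solver.y, False, solver.t


def _polish_root(rhs, state: np.ndarray) -> np.ndarray:
    """Refine a near-steady state by solving RHS = 0 directly.

    Accepted only when the root solver stays in the same basin (small
    move, non-negative concentrations); otherwise the integrated state
    is returned unchanged.
    """
    sol = root(lambda s: rhs(0.0, s), state, method="hybr")
    if (
        sol.success
        and np.all(np.isfinite(sol.x))
        and np.max(np.abs(sol.x - state)) < 1e-2
        and np.all(sol.x > -1e-9)
    ):
        return np.maximum(sol.x, 0.0)
    return state


def find_steady_state(
    params: KineticParameters,
    effective_m: np.ndarray | None = None,
    init: np.ndarray | None = None,
    tol: float = STEADY_TOL,
    max_steps: int = MAX_STEPS,
    seed: int | None = None,
    detector: str = "residual",
) -> tuple[np.ndarray, bool]:
    """Integrate to a steady state from `init` or a random start.

    The random start draws every mRNA and protein concentration from
    Uniform(0, 1).  Returns the stacked state ``[x, y]`` and a flag
    telling whether the residual test converged within `max_steps`
    accepted solver steps; for oscillating (cyclic) systems the flag is
    False and the last state is returned.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    n = params.n_genes
    if init is None:
        rng = np.random.default_rng(seed)
        init = rng.uniform(0.0, 1.0, size=2 * n)
    init = np.asarray(init, dtype=float)
    if init.shape[0] != 2 * n:
        raise SimulationError(f"initial state must have length {2 * n}")
    rhs = make_rhs(params, effective_m)
    state, converged, _ = _integrate_to_steady(rhs, init, tol, max_steps, detector)
    return np.maximum(state, 0.0), converged


def _timepoint_grid(t_span, n_timepoints: int, spacing: str) -> np.ndarray:
    t0, t1 = t_span
    if spacing == "linear":
        return np.linspace(t0, t1, n_timepoints)
    if spacing == "log":
        # points dense early, sparse late; first point at t0 exactly
        frac = (np.logspace(0.0, 1.0, n_timepoints) - 1.0) / 9.0
        return t0 + (t1 - t0) * frac
    raise ValueError(f"spacing must be 'linear' or 'log', got {spacing!r}")


def simulate_experiment(
    params: KineticParameters,
    design_row: np.ndarray,
    control_state: np.ndarray,
    mode: str = "steady",
    t_span=DEFAULT_T_SPAN,
    n_timepoints: int = DEFAULT_N_TIMEPOINTS,
    spacing: str = "linear",
    tol: float = STEADY_TOL,
    max_steps: int = MAX_STEPS,
):
    """Simulate one perturbation experiment from the control state.

    Steady mode returns ``(state, converged)`` with the stacked endpoint;
    time-series mode returns ``(states, timepoints)`` where states is
    (2*n_genes) x n_timepoints.
    """
    n = params.n_genes
    design_row = np.asarray(design_row, dtype=float)
    effective_m = apply_perturbation(params.m, design_row)
    rhs = make_rhs(params, effective_m)
    if mode == "steady":
        state, converged, _ = _integrate_to_steady(
            rhs, control_state, tol=tol, max_steps=max_steps
        )
        return np.maximum(state, 0.0), converged
    if mode == "timeseries":
        tps = _timepoint_grid(t_span, n_timepoints, spacing)
        sol = solve_ivp(
            rhs, (tps[0], tps[-1]), np.asarray(control_state, dtype=float),
            method="LSODA", t_eval=tps, rtol=SOLVER_TOL, atol=SOLVER_TOL,
        )
        if not sol.success:
            raise SimulationError(f"ODE solver failed: {sol.message}")
        return np.maximum(sol.y, 0.0), tps
    raise ValueError(f"mode must be 'steady' or 'timeseries', got {mode!r}")


def run_design(
    params: KineticParameters,
    design: PerturbationDesign,
    replicates: int = 1,
    mode: str = "steady",
    noise_config: NoiseConfig | None = None,
    t_span=DEFAULT_T_SPAN,
    n_timepoints: int = DEFAULT_N_TIMEPOINTS,
    spacing: str = "linear",
    keep_protein: bool = False,
    seed: int | None = None,
    tol: float = STEADY_TOL,
    max_steps: int = MAX_STEPS,
) -> ExpressionDataset:
    """Simulate every experiment of a design and assemble a dataset.

    The control is solved once from a random start; each design row is
    solved once (the ODE is deterministic) and replicated; replicate
    variation comes only from the noise model.  Noise realizations are
    recorded alongside the data.
    """
    if replicates < 1:
        raise ValueError("at least one replicate required")
    if design.genes != params.genes:
        raise SimulationError("design gene list does not match the kinetic model")
    n = params.n_genes
    rng = np.random.default_rng(seed)
    control_state, control_ok = find_steady_state(
        params, tol=tol, max_steps=max_steps, seed=int(rng.integers(2**31))
    )
    control_x = control_state[:n]

    per_experiment = []
    conv_flags = []
    tps = None
    for i in range(design.n_experiments):
        try:
            if mode == "steady":
                state, ok = simulate_experiment(
                    params, design.matrix[i], control_state, mode="steady",
                    tol=tol, max_steps=max_steps,
                )
                per_experiment.append(state)
                conv_flags.append(ok)
            else:
                states, tps = simulate_experiment(
                    params, design.matrix[i], control_state, mode="timeseries",
                    t_span=t_span, n_timepoints=n_timepoints, spacing=spacing,
                )
                per_experiment.append(states)
                conv_flags.append(True)
        except SimulationError as exc:
            raise SimulationError(f"experiment {design.labels[i]!r}: {exc}") from exc

    rows, labels, rep_idx, exp_idx = [], [], [], []
    for i, result in enumerate(per_experiment):
        for rep in range(replicates):
            if mode == "steady":
                rows.append(result[:n])
            else:
                rows.append(result[:n, :])
            labels.append(f"{design.labels[i]}_r{rep}" if replicates > 1
                          else design.labels[i])
            rep_idx.append(rep)
            exp_idx.append(i)
    clean = np.stack(rows)

    protein = None
    if keep_protein and mode == "steady":
        protein = np.stack([per_experiment[e][n:] for e in exp_idx])

    if noise_config is not None:
        noisy, realized = apply_noise(
            clean, noise_config, seed=int(rng.integers(2**31))
        )
    else:
        noisy = clean.copy()
        realized = np.ones_like(clean)

    return ExpressionDataset(
        genes=list(params.genes),
        values=noisy,
        clean_values=clean,
        control=control_x,
        protein_values=protein,
        timepoints=tps,
        replicates=np.asarray(rep_idx),
        experiment=np.asarray(exp_idx),
        labels=labels,
        noise_applied=realized,
        converged=np.repeat(np.asarray(conv_flags, dtype=bool), replicates),
        metadata={
            "mode": mode,
            "replicates": replicates,
            "control_converged": bool(control_ok),
            "seed": seed,
            "noise": None if noise_config is None else noise_config.describe(),
            "scheme": design.scheme,
        },
    )


FOLD_CHANGE_FLOOR = 1e-9


def to_fold_change(dataset: ExpressionDataset) -> np.ndarray:
    """log2 fold change of every value against the control steady state.

    Control values are floored at 1e-9 before division so knockouts that
    drive a concentration to numerical zero stay finite; noisy values at
    or below zero are floored the same way.
    """
    control = np.maximum(dataset.control, FOLD_CHANGE_FLOOR)
    values = np.maximum(dataset.values, FOLD_CHANGE_FLOOR)
    if dataset.values.ndim == 2:
        return np.log2(values / control[None, :])
    return np.log2(values / control[None, :, None])
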