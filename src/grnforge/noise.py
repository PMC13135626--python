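"""Measurement-noise models applied to simulated expression data.

Three built-in models plus a user-supplied escape hatch:

- **gaussian** (default): each value s is multiplied by a factor
  drawn from Normal(mean 1, sd sigma).
- **lognormal**: multiplicative factor with ln(eps) ~ Normal(-sigma^2/2,
  sigma^2), so E[eps] = 1; appropriate for microarray-like data.  Factors
  are strictly positive, so signs are preserved.
- **single_cell**: zero-inflated negative binomial read counts.  Expected
  reads per gene are proportional to expression times gene length,
  normalized so the dataset-wide expectation equals the requested
  coverage; overdispersion derives from the error rate (error_rate -> 0
  recovers Poisson); dropout zeroes low-expression genes preferentially.
- **custom**: a same-shaped matrix added entry-wise, or a callable
  ``f(data, seed) -> matrix``.

The noise level of the multiplicative models can be set either directly
through sigma or through a target signal-to-noise ratio SNR = s/sigma,
where the dataset-level signal s is taken as the median absolute value
(robust to knockout zeros).

All functions are pure: the input is never modified, and the realized
noise is returned alongside the noisy data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NoiseConfig",
    "NoiseError",
    "gaussian_noise",
    "lognormal_noise",
    "single_cell_noise",
    "custom_noise",
    "snr_to_sigma",
    "apply_noise",
]

DROPOUT_DECAY = 1.0


class NoiseError(ValueError):
    """Invalid noise configuration."""


@dataclass
class NoiseConfig:
    """Configuration of one noise model.

    Exactly one of `sigma` / `snr` must be set for the gaussian and
    lognormal models; `sc_params` is required for (and exclusive to) the
    single-cell model; `custom` carries the user matrix or callable.
    """

    model: str = "gaussian"
    sigma: float | None = None
    snr: float | None = None
    sc_params: dict | None = None
    custom: object = None
    clamp0: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model in ("gaussian", "lognormal"):
            if (self.sigma is None) == (self.snr is None):
                raise NoiseError("set exactly one of sigma or snr")
            if self.sigma is not None and self.sigma < 0:
                raise NoiseError("sigma must be non-negative")
            if self.snr is not None and self.snr <= 0:
                raise NoiseError("snr must be positive")
        elif self.model == "single_cell":
            if not self.sc_params:
                raise NoiseError("single_cell model requires sc_params")
        elif self.model == "custom":
            if self.custom is None:
                raise NoiseError("custom model requires a matrix or callable")
        else:
            raise NoiseError(f"unknown noise model {self.model!r}")

    def resolve_sigma(self, data: np.ndarray) -> float:
        if self.sigma is not None:
            return self.sigma
        return snr_to_sigma(data, self.snr)

    def describe(self) -> dict:
        return {"model": self.model, "sigma": self.sigma, "snr": self.snr,
                "sc_params": self.sc_params, "seed": self.seed}


def snr_to_sigma(data: np.ndarray, snr: float) -> float:
    """Noise sd for a target SNR = s/sigma with s = median(|data|)."""
    if snr <= 0:
        raise NoiseError("snr must be positive")
    s_ref = float(np.median(np.abs(np.asarray(data))))
    if s_ref == 0:
        raise NoiseError("signal is identically zero; SNR is undefined")
    return s_ref / snr


def gaussian_noise(
    data: np.ndarray, config: NoiseConfig, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Multiply each entry by a Normal(1, sigma) factor.

    Values are not clamped by default: mean-one multiplicative noise with
    a large sigma can flip signs, and for fold-change-scale data that is
    meaningful.  Set ``config.clamp0`` to floor the output at zero for
    concentration-scale data.
    """
    data = np.asarray(data, dtype=float)
    sigma = config.resolve_sigma(data)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    eps = rng.normal(1.0, sigma, size=data.shape)
    noisy = data * eps
    if config.clamp0:
        noisy = np.maximum(noisy, 0.0)
    return noisy, eps


def lognormal_noise(
    data: np.ndarray, config: NoiseConfig, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Multiply each entry by a log-normal factor with unit mean.

    ln(eps) ~ Normal(-sigma^2/2, sigma^2) so that E[eps] = 1; all factors
    are positive, so the data's signs are preserved.
    """
    data = np.asarray(data, dtype=float)
    sigma = config.resolve_sigma(data)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    eps = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=data.shape)
    return data * eps, eps


def single_cell_noise(
    data: np.ndarray, config: NoiseConfig, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-inflated negative binomial sequencing counts.

    Parameters in ``config.sc_params``:

    coverage : float
        Expected total reads over the whole dataset.
    gene_length : array-like, optional
        Per-gene positive lengths (default all equal); expected reads per
        entry are proportional to expression * length.
    error_rate : float in [0, 1)
        Sets the NB dispersion ``d = 1/error_rate - 1`` (NB variance
        mu + mu^2/d); 0 recovers Poisson counts.
    dropout_rate : float in [0, 1)
        Maximum zero-inflation probability; an entry with expected reads
        lam drops out with probability ``dropout_rate * exp(-lam)``, so
        dropout concentrates in low-expression genes.

    Returns the integer count matrix and the realized counts themselves
    (the "noise" of a counting model is the count realization).
    """
    data = np.asarray(data, dtype=float)
    if np.any(data < 0):
        raise NoiseError("single-cell noise requires non-negative expression")
    p = dict(config.sc_params or {})
    coverage = float(p.get("coverage", 1e6))
    error_rate = float(p.get("error_rate", 0.05))
    dropout_rate = float(p.get("dropout_rate", 0.3))
    if not 0 <= error_rate < 1:
        raise NoiseError("error_rate must be in [0, 1)")
    if not 0 <= dropout_rate <= 1:
        raise NoiseError("dropout_rate must be in [0, 1]")
    n_genes = data.shape[-1] if data.ndim > 1 else data.shape[0]
    length = np.asarray(p.get("gene_length", np.ones(n_genes)), dtype=float)
    if np.any(length <= 0):
        raise NoiseError("gene lengths must be positive")

    weighted = data * length  # broadcast over trailing gene axis? see below
    if data.ndim == 2:
        weighted = data * length[None, :]
    total = weighted.sum()
    lam = np.zeros_like(weighted) if total == 0 else weighted * (coverage / total)

    rng = np.random.default_rng(config.seed if seed is None else seed)
    if error_rate == 0:
        counts = rng.poisson(lam)
    else:
        d = 1.0 / error_rate - 1.0
        # NB with mean lam and shape d: p = d / (d + lam)
        counts = np.zeros_like(lam, dtype=np.int64)
        pos = lam > 0
        counts[pos] = rng.negative_binomial(d, d / (d + lam[pos]))
    drop = rng.random(lam.shape) < dropout_rate * np.exp(-lam * DROPOUT_DECAY)
    counts = np.where(drop, 0, counts)
    return counts.astype(np.int64), counts.astype(np.int64)


def custom_noise(
    data: np.ndarray, noise, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a user-supplied noise matrix (added) or callable.

    A matrix must match the data's shape and is added entry-wise.  A
    callable receives ``(data, seed)`` and must return a same-shaped
    noisy matrix; the realization reported is ``result - data``.
    """
    data = np.asarray(data, dtype=float)
    if callable(noise):
        noisy = np.asarray(noise(data, seed), dtype=float)
        if noisy.shape != data.shape:
            raise NoiseError(
                f"noise callable returned shape {noisy.shape}, expected {data.shape}"
            )
        return noisy, noisy - data
    mat = np.asarray(noise, dtype=float)
    if mat.shape != data.shape:
        raise NoiseError(f"noise matrix shape {mat.shape} does not match data {data.shape}")
    return data + mat, mat


def apply_noise(
    data: np.ndarray, config: NoiseConfig, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Dispatch to the configured noise model."""
    if config.model == "gaussian":
        return gaussian_noise(data, config, seed)
    if config.model == "lognormal":
        return lognormal_noise(data, config, seed)
    if config.model == "single_cell":
        return single_cell_noise(data, config, seed)
    if config.model == "custom":
        return custom_noise(data, config.custom, seed)
    raise NoiseError(f"unknown noise model {config.model!r}")
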