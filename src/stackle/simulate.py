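"""Synthetic data with the structure of a sparse interacting-effects study.

The regression generator draws an n × p matrix of independent standard-normal
explanatory variables, gives the first ``n_causal`` of them unit main-effect
coefficients, adds unit-coefficient interactions between neighboring causal
variables (x1·x2, x2·x3, ..., so n_causal − 1 pairs), and then adds Gaussian
noise scaled so that var(signal)/var(noise) equals the requested
signal-to-noise ratio.  At the defaults (n=1000, p=200, n_causal=20, snr=4)
the attainable prediction accuracy is bounded by
corr(signal, Y) = sqrt(snr/(1+snr)) = sqrt(0.8) ≈ 0.894.

The classification generator reuses the latent signal and quantile-bins the
noisy latent into ordered categories with deliberately unequal bin widths, so
minor classes exist — the regime where radial-kernel SVMs tend to miss rare
categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .exceptions import InputError

_DEFAULT_N = 1000
_DEFAULT_P = 200
_DEFAULT_CAUSAL = 20
_DEFAULT_SNR = 4.0


@dataclass
class SimulatedDataset:
    """One simulated dataset plus the ground truth that generated it."""

    X: np.ndarray
    Y: np.ndarray
    beta: np.ndarray
    interaction_pairs: list[tuple[int, int]]
    noise_sd: float
    seed: int
    signal: np.ndarray

    @property
    def n(self) -> int:
        return len(self.Y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return [f"x{j}" for j in range(self.p)]


def _latent(n: int, p: int, n_causal: int, interactions: str, rng: np.random.Generator):
    if n_causal > p:
        raise InputError(f"n_causal ({n_causal}) cannot exceed p ({p})")
    if n_causal < 1:
        raise InputError("n_causal must be >= 1")
    if interactions not in ("causal", "all"):
        raise InputError("interactions must be 'causal' or 'all'")
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[:n_causal] = 1.0
    last = n_causal if interactions == "causal" else p
    pairs = [(j, j + 1) for j in range(last - 1)]
    signal = X @ beta
    for j, k in pairs:
        signal = signal + X[:, j] * X[:, k]
    return X, beta, pairs, signal


def simulate_regression(
    n: int = _DEFAULT_N,
    p: int = _DEFAULT_P,
    n_causal: int = _DEFAULT_CAUSAL,
    snr: float = _DEFAULT_SNR,
    seed: int = 0,
    interactions: str = "causal",
) -> SimulatedDataset:
    """Generate one regression dataset; a pure function of its arguments.

    ``noise_sd`` is set from the realized sample standard deviation of the
    signal, ``sd(signal)/sqrt(snr)``, so the variance-ratio invariant holds by
    construction on the drawn data.  Generate a companion test set by calling
    again with an independent seed.
    """
    if snr <= 0:
        raise InputError(f"snr must be positive, got {snr}")
    rng = np.random.default_rng(seed)
    X, beta, pairs, signal = _latent(n, p, n_causal, interactions, rng)
    noise_sd = float(np.std(signal, ddof=1) / np.sqrt(snr))
    Y = signal + rng.normal(0.0, noise_sd, size=n)
    return SimulatedDataset(X=X, Y=Y, beta=beta, interaction_pairs=pairs,
                            noise_sd=noise_sd, seed=seed, signal=signal)


def simulate_classification(
    n: int = _DEFAULT_N,
    p: int = _DEFAULT_P,
    n_causal: int = _DEFAULT_CAUSAL,
    n_classes: int = 4,
    seed: int = 0,
    snr: float = _DEFAULT_SNR,
    class_probs: Optional[Sequence[float]] = None,
) -> SimulatedDataset:
    """Generate a classification dataset by quantile-binning the noisy latent.

    Default class probabilities are proportional to 1..n_classes (e.g.
    0.1/0.2/0.3/0.4 for four classes), giving ordered categories with genuine
    minor classes.  Labels are strings ``"c1" .. "cK"``.
    """
    if n_classes < 2:
        raise InputError(f"n_classes must be >= 2, got {n_classes}")
    if n_classes > n:
        raise InputError(f"n_classes ({n_classes}) cannot exceed n ({n})")
    if class_probs is None:
        w = np.arange(1, n_classes + 1, dtype=float)
        class_probs = w / w.sum()
    probs = np.asarray(class_probs, dtype=float)
    if len(probs) != n_classes or probs.min() <= 0 or abs(probs.sum() - 1) > 1e-9:
        raise InputError("class_probs must be n_classes positive values summing to 1")
    rng = np.random.default_rng(seed)
    X, beta, pairs, signal = _latent(n, p, n_causal, "causal", rng)
    noise_sd = float(np.std(signal, ddof=1) / np.sqrt(snr))
    latent = signal + rng.normal(0.0, noise_sd, size=n)
    # unequal-width bins at the latent's theoretical-ish quantiles
    edges = np.quantile(latent, np.cumsum(probs)[:-1])
    codes = np.searchsorted(edges, latent, side="right")
    Y = np.array([f"c{k + 1}" for k in codes], dtype=object)
    return SimulatedDataset(X=X, Y=Y, beta=beta, interaction_pairs=pairs,
                            noise_sd=noise_sd, seed=seed, signal=signal)
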