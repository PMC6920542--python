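"""MCMC convergence diagnostics: split-Rhat and effective sample size.

Lightweight implementations of the standard split-chain potential scale
reduction factor and the Geyer initial-monotone-sequence effective sample
size, suitable for calling once per fitted replicate inside large
simulation grids.
"""

from __future__ import annotations

import numpy as np

__all__ = ["split_rhat", "ess"]


def _split(chains: np.ndarray) -> np.ndarray:
    """Split each chain in half, doubling the chain count."""
    c, n = chains.shape
    half = n // 2
    return np.concatenate([chains[:, :half], chains[:, n - half :]], axis=0)


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (Gelman–Rubin, rank-free form).

    ``chains`` is (n_chains, n_draws); each chain is split in half first so
    within-chain drift also registers.
    """
    x = _split(np.asarray(chains, dtype=float))
    m, n = x.shape
    if n < 4:
        return float("nan")
    means = x.mean(axis=1)
    variances = x.var(axis=1, ddof=1)
    W = variances.mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def ess(chains: np.ndarray) -> float:
    """Effective sample size via Geyer's initial monotone positive sequence.

    Autocovariances are estimated per chain by FFT, averaged, and summed over
    successive lag pairs until a pair sum goes non-positive; the running
    pair-sum sequence is also forced non-increasing (monotone estimator).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    m, n = x.shape
    if n < 4:
        return float("nan")
    xc = x - x.mean(axis=1, keepdims=True)
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, size, axis=1)
    acov = np.fft.irfft(f * np.conj(f), size, axis=1)[:, :n].real / n
    rho = acov.mean(axis=0)
    if rho[0] == 0:
        return float(m * n)
    rho = rho / rho[0]
    # Geyer pairs P_t = rho[2t] + rho[2t+1]; keep while positive, force monotone
    pair_sums = []
    t = 0
    while 2 * t + 1 < n:
        p = rho[2 * t] + rho[2 * t + 1]
        if p <= 0:
            break
        pair_sums.append(p)
        t += 1
    if pair_sums:
        pair_sums = np.minimum.accumulate(pair_sums)
        tau = max(2.0 * float(np.sum(pair_sums)) - 1.0, 1.0 / (m * n))
    else:
        tau = 1.0
    return float(m * n / tau)
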