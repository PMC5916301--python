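"""Chain diagnostics: Geweke convergence score and highest-density intervals."""

from __future__ import annotations

import numpy as np


def _spectrum0(x: np.ndarray) -> float:
    """Spectral density of a chain at frequency zero, per sample.

    Newey-West estimator with a Bartlett window; lag span grows as the cube
    root of the segment length, the usual compromise between bias and
    variance for MCMC output.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    L = max(1, int(np.floor(4 * (n / 100.0) ** (1.0 / 3.0) * 2)))
    L = min(L, n - 1)
    s = xc @ xc / n
    for lag in range(1, L + 1):
        w = 1.0 - lag / (L + 1.0)
        s += 2.0 * w * (xc[:-lag] @ xc[lag:]) / n
    return float(max(s, 0.0))


def geweke(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain means.

    z = (mean_first - mean_last) / sqrt(S1/n1 + S2/n2) with S the spectral
    density at zero of each window. |z| beyond ~2 flags non-convergence.
    """
    chain = np.asarray(chain, dtype=float)
    n = len(chain)
    if n < 100:
        raise ValueError("chain too short for a Geweke score (need >= 100)")
    a = chain[: int(first * n)]
    b = chain[n - int(last * n):]
    if np.var(chain) == 0:
        raise ValueError("zero-variance chain: Geweke score undefined")
    va = _spectrum0(a) / len(a)
    vb = _spectrum0(b) / len(b)
    return float((a.mean() - b.mean()) / np.sqrt(va + vb))


def hpdi(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``level`` posterior mass (sample version).

    Scans all windows of ceil(level * n) consecutive sorted draws and returns
    the narrowest; exact for unimodal samples.
    """
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 draws")
    m = int(np.ceil(level * n))
    m = min(max(m, 1), n)
    if m == n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m - 1])
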