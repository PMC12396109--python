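"""MCMC convergence diagnostics for flux-sampling chains.

Two classic tests guard against under- and over-sampling of the solution
space: Geweke's stationarity z-score (early versus late segment means) and
the Raftery-Lewis run-length procedure (chain length needed to estimate a
tail quantile to a stated accuracy and confidence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "ChainTooShortError",
    "geweke_z",
    "RafteryLewisResult",
    "raftery_lewis",
    "raftery_lewis_nmin",
]


class ChainTooShortError(ValueError):
    pass


def _spectral_var0(x: np.ndarray) -> float:
    """Spectral density of ``x`` at frequency zero (Bartlett window over 4% of lags).

    Falls back to the plain sample variance when the windowed estimate is
    non-positive (possible for strongly antithetic chains).
    """
    n = len(x)
    xc = x - x.mean()
    gamma0 = float(xc @ xc) / n
    if gamma0 == 0.0:
        return 0.0
    lags = max(1, int(0.04 * n))
    s = gamma0
    for k in range(1, lags + 1):
        w = 1.0 - k / (lags + 1.0)
        s += 2.0 * w * float(xc[:-k] @ xc[k:]) / n
    return s if s > 0 else gamma0


def geweke_z(
    chain: np.ndarray,
    first_frac: float = 0.1,
    last_frac: float = 0.5,
    spectral: bool = True,
) -> float:
    """Geweke stationarity z-score between the first and last chain segments.

    ``z = (mean_first - mean_last) / sqrt(var_first/n_first + var_last/n_last)``
    with segment variances estimated as spectral density at zero (or plain
    sample variance when ``spectral=False``).  A chain whose segments both
    have zero variance scores 0; |z| > 1.96 flags non-stationarity at the
    5% level.
    """
    chain = np.asarray(chain, dtype=float)
    n = len(chain)
    if n < 20:
        raise ChainTooShortError(f"Geweke needs a chain of >= 20 points, got {n}")
    scale = max(float(np.abs(chain).max()), 1.0)
    if float(np.var(chain)) <= (1e-12 * scale) ** 2:  # constant chain up to rounding
        return 0.0
    n1 = max(1, int(first_frac * n))
    n2 = max(1, int(last_frac * n))
    first, last = chain[:n1], chain[n - n2 :]
    est = _spectral_var0 if spectral else lambda x: float(np.var(x))
    v1, v2 = est(first), est(last)
    denom = math.sqrt(v1 / n1 + v2 / n2)
    diff = float(first.mean() - last.mean())
    if denom == 0.0:
        return 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    return diff / denom


@dataclass
class RafteryLewisResult:
    n_required: int  # chain length needed (burn-in included)
    burn_in: int
    thin_k: int  # smallest thinning at which first-order Markov suffices
    alpha: float  # P(below -> above threshold)
    beta: float  # P(above -> below threshold)
    n_min_independent: int  # requirement for an iid chain


def _g2_second_vs_first(z: np.ndarray) -> tuple[float, int]:
    """G2 statistic testing a second-order Markov chain against first-order."""
    trip = z[:-2] * 4 + z[1:-1] * 2 + z[2:]
    counts = np.bincount(trip, minlength=8).reshape(2, 2, 2).astype(float)
    n_ij = counts.sum(axis=2)  # transitions (i, j)
    n_jl = counts.sum(axis=0)  # transitions (j, l)
    n_j = counts.sum(axis=(0, 2))
    g2 = 0.0
    for i in range(2):
        for j in range(2):
            for l in range(2):
                o = counts[i, j, l]
                if o > 0 and n_j[j] > 0:
                    e = n_ij[i, j] * n_jl[j, l] / n_j[j]
                    g2 += 2.0 * o * math.log(o / e)
    return g2, int(counts.sum())


def raftery_lewis(
    chain: np.ndarray, q: float = 0.025, r: float = 0.005, s: float = 0.95
) -> RafteryLewisResult:
    """Raftery-Lewis run-length diagnostic for estimating quantile ``q``
    to within ``+-r`` with probability ``s``.

    The chain is binarized at its empirical q-quantile; the smallest
    thinning ``k`` at which a first-order two-state Markov chain is
    preferred over second-order (BIC) is found, transition probabilities
    are estimated, and the required length is
    ``k * (2-a-b)ab/(a+b)^3 * (z_{(s+1)/2}/r)^2`` plus burn-in.
    """
    chain = np.asarray(chain, dtype=float)
    phi = float(norm.ppf((s + 1.0) / 2.0))
    n_min = int(math.ceil(phi * phi / (r * r) * q * (1.0 - q)))
    if len(chain) < n_min:
        raise ChainTooShortError(
            f"Raftery-Lewis needs at least {n_min} samples for q={q}, r={r}, s={s}; "
            f"got {len(chain)}"
        )
    u = np.quantile(chain, q)
    z = (chain <= u).astype(np.int64)

    k = 1
    while True:
        zk = z[::k]
        if len(zk) < 8 or k > len(chain) // 8:
            break
        g2, m = _g2_second_vs_first(zk)
        bic = g2 - 2.0 * math.log(max(m, 1))
        if bic < 0:
            break
        k += 1

    zk = z[::k]
    pairs = zk[:-1] * 2 + zk[1:]
    c = np.bincount(pairs, minlength=4).astype(float)
    n0 = c[0] + c[1]
    n1 = c[2] + c[3]
    alpha = c[1] / n0 if n0 > 0 else 0.0  # 0 -> 1
    beta = c[2] / n1 if n1 > 0 else 0.0  # 1 -> 0
    if alpha <= 0 or beta <= 0:
        # chain never leaves one state at this thinning: report the
        # independence requirement as a floor rather than dividing by zero
        return RafteryLewisResult(n_min, 0, k, alpha, beta, n_min)

    factor = (2.0 - alpha - beta) * alpha * beta / (alpha + beta) ** 3
    n_keep = k * factor * (phi / r) ** 2
    lam = abs(1.0 - alpha - beta)
    if 0 < lam < 1:
        burn = k * math.log(0.001 * (alpha + beta) / max(alpha, beta)) / math.log(lam)
        burn_in = int(math.ceil(max(burn, 0.0)))
    else:
        burn_in = k
    return RafteryLewisResult(
        n_required=int(math.ceil(n_keep)) + burn_in,
        burn_in=burn_in,
        thin_k=k,
        alpha=float(alpha),
        beta=float(beta),
        n_min_independent=n_min,
    )


def raftery_lewis_nmin(
    chain: np.ndarray, q: float = 0.025, r: float = 0.005, s: float = 0.95
) -> int:
    """Required chain length (burn-in included) from the Raftery-Lewis procedure."""
    return raftery_lewis(chain, q=q, r=r, s=s).n_required
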