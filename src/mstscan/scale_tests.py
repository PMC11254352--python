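"""Multivariate (MST) and univariate (UST) scale tests.

Both tests ask whether the dispersion measure D (median-centered squared
residuals of K traits) shifts with genotype at one SNP.  The reduced model
fits a common mean vector; the larger model adds genotype-group dummies.
With residual sums-of-squares-and-cross-products matrices S0 (reduced) and
S1 (larger),

* the MST statistic is Pillai's trace V = tr[(S0 - S1) S0^-1], transformed
  to F = [V / (s - V)] * (df2 / df1) with s = min(K, L-1),
  t = (|K - L + 1| - 1)/2, u = (n - L - K - 1)/2, df1 = s(2t + s + 1),
  df2 = s(2u + s + 1);

* the UST for trait k is F = [(S0[k,k] - S1[k,k]) / S1[k,k]] * (df4/df3)
  with df3 = L - 1 and df4 = n - L, i.e. the one-way ANOVA F of D_k on
  genotype group (the Brown-Forsythe scale test).

The SSCP matrices are raw sums of outer products (no 1/n); any common
scaling cancels in V and in the univariate ratio.  p-values are evaluated
through the F log-survival function so that magnitudes like 1e-215 are
representable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateTraitSetError, UntestableSNPError
from .preprocess import DispersionMatrix

#: |V - s| below this is treated as a boundary (perfect-fit) case
V_CLIP_TOL = 1e-10


@dataclass
class MSTResult:
    """Pillai's trace test of genotype effect on the K-trait dispersion."""

    V: float
    F: float
    s: float
    t: float
    u: float
    df1: float
    df2: float
    p: float
    log10_p: float
    Sigma0: np.ndarray
    Sigma1: np.ndarray
    gamma: np.ndarray  # (1 + L - 1) x K coefficients of the larger model
    n_used: int
    L: int


@dataclass
class USTResult:
    """One-way ANOVA F of one trait's dispersion on genotype group."""

    F: float
    df3: float
    df4: float
    p: float
    log10_p: float
    trait_index: int
    degenerate: bool = False


def genotype_dummies(g: np.ndarray) -> tuple[np.ndarray, int]:
    """Dummy-code observed genotype groups.

    The reference group is 0 minor alleles when present, otherwise the
    lowest observed count; one column per non-reference group, so three
    observed genotypes give the coding (0,0), (1,0), (0,1) for 0/1/2 minor
    alleles.  Raises :class:`UntestableSNPError` when the SNP is monomorphic
    in the analysed samples.
    """
    g = np.asarray(g, dtype=float)
    if np.isnan(g).any():
        raise ValueError("genotype_dummies expects complete (non-missing) calls")
    levels = np.unique(g)
    L = levels.size
    if L < 2:
        raise UntestableSNPError(f"monomorphic in analysed samples (L={L})")
    dummies = (g[:, None] == levels[1:][None, :]).astype(float)
    return dummies, L


def pillai_df(K: int, L: int, n: int) -> tuple[float, float, float, float, float]:
    """Degrees-of-freedom scalars of the Pillai F approximation.

    Returns (s, t, u, df1, df2) for K responses, L groups, n samples.
    """
    if n <= L + K + 1:
        raise ValueError(f"n={n} too small for K={K}, L={L}: need n > L + K + 1")
    s = float(min(K, L - 1))
    t = (abs(K - L + 1) - 1) / 2.0
    u = (n - L - K - 1) / 2.0
    df1 = s * (2 * t + s + 1)
    df2 = s * (2 * u + s + 1)
    return s, t, u, df1, df2


def _sscp_pair(D: np.ndarray, dummies: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Residual SSCP under the reduced (intercept) and larger (+dummies)
    models, plus the larger model's coefficient matrix."""
    n = D.shape[0]
    Dc = D - D.mean(axis=0)
    S0 = Dc.T @ Dc
    design = np.hstack([np.ones((n, 1)), dummies])
    gamma, _, _, _ = np.linalg.lstsq(design, D, rcond=None)
    R1 = D - design @ gamma
    S1 = R1.T @ R1
    return S0, S1, gamma


def _log10_f_sf(F: float, df1: float, df2: float) -> float:
    return stats.f.logsf(F, df1, df2) / np.log(10.0)


def mst(D: DispersionMatrix | np.ndarray, dummies: np.ndarray, L: int,
        n_used: int | None = None) -> MSTResult:
    """Multivariate scale test of a genotype grouping on the dispersion matrix."""
    Dm = D.D if isinstance(D, DispersionMatrix) else np.asarray(D, dtype=float)
    if Dm.ndim == 1:
        Dm = Dm[:, None]
    n, K = Dm.shape
    if n_used is None:
        n_used = n
    s, t, u, df1, df2 = pillai_df(K, L, n_used)
    S0, S1, gamma = _sscp_pair(Dm, dummies)

    try:
        np.linalg.cholesky(S0)  # PD check with a clearer failure than solve's
        S0_inv_H = np.linalg.solve(S0, S0 - S1)
    except np.linalg.LinAlgError as exc:
        raise DegenerateTraitSetError(
            f"reduced-model SSCP is singular ({exc}); "
            "check for duplicated or constant traits") from exc
    V = float(np.trace(S0_inv_H))
    if V > s + V_CLIP_TOL or V < -V_CLIP_TOL:
        raise DegenerateTraitSetError(
            f"Pillai's trace V={V} outside [0, s={s}] beyond tolerance")
    V = float(np.clip(V, 0.0, s))

    if s - V <= V_CLIP_TOL:
        # larger model fits perfectly in every direction: boundary case
        F, p, lp = np.inf, 0.0, -np.inf
    else:
        F = (V / (s - V)) * (df2 / df1)
        lp = _log10_f_sf(F, df1, df2)
        p = float(stats.f.sf(F, df1, df2))
    return MSTResult(V=V, F=float(F), s=s, t=t, u=u, df1=df1, df2=df2,
                     p=p, log10_p=lp, Sigma0=S0, Sigma1=S1, gamma=gamma,
                     n_used=n_used, L=L)


def ust(D_k: np.ndarray, dummies: np.ndarray, L: int,
        n_used: int | None = None, trait_index: int = 0) -> USTResult:
    """Univariate scale test: one-way ANOVA F of one trait's dispersion."""
    D_k = np.asarray(D_k, dtype=float).reshape(-1)
    n = D_k.size
    if n_used is None:
        n_used = n
    S0, S1, _ = _sscp_pair(D_k[:, None], dummies)
    return _ust_from_ss(float(S0[0, 0]), float(S1[0, 0]), L, n_used, trait_index)


def ust_from_sscp(result: MSTResult) -> list[USTResult]:
    """Per-trait USTs from an MST's SSCP pair (same quantities, no refit)."""
    return [_ust_from_ss(float(result.Sigma0[k, k]), float(result.Sigma1[k, k]),
                         result.L, result.n_used, k)
            for k in range(result.Sigma0.shape[0])]


def _ust_from_ss(ss0: float, ss1: float, L: int, n_used: int,
                 trait_index: int) -> USTResult:
    if n_used <= L:
        raise ValueError(f"n={n_used} too small for L={L} groups")
    df3 = float(L - 1)
    df4 = float(n_used - L)
    if ss1 <= max(ss0, 1.0) * 1e-12:  # within-group SS numerically zero
        if ss0 <= 0.0:  # constant dispersion: no evidence either way
            return USTResult(F=0.0, df3=df3, df4=df4, p=1.0, log10_p=0.0,
                             trait_index=trait_index)
        return USTResult(F=np.inf, df3=df3, df4=df4, p=0.0, log10_p=-np.inf,
                         trait_index=trait_index, degenerate=True)
    F = max(0.0, (ss0 - ss1) / ss1) * (df4 / df3)
    return USTResult(F=float(F), df3=df3, df4=df4,
                     p=float(stats.f.sf(F, df3, df4)),
                     log10_p=_log10_f_sf(F, df3, df4),
                     trait_index=trait_index)
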