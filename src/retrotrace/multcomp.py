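"""Dunnett's many-to-one comparison test.

Compares each treatment group against a shared control with a pooled
variance estimate.  Under the null the vector of comparison statistics
follows a multivariate t distribution with the one-factor correlation
structure corr(T_i, T_j) = lambda_i * lambda_j, lambda_i =
sqrt(n_i / (n_i + n0)).  Two-sided family-wise p-values are computed by
deterministic quadrature over the shared control deviate and the pooled
scale (Gauss-Hermite x Gauss-Legendre in quantile space), so results are
reproducible to ~1e-8; with a single comparison the test reduces exactly
to the classical two-sample pooled t test.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats

_GH_NODES = 80
_GL_NODES = 80


class MultCompError(ValueError):
    pass


def _max_abs_t_cdf(q: float, lambdas: np.ndarray, df: int) -> float:
    """P(max_j |T_j| <= q) for the Dunnett one-factor multivariate t."""
    if q <= 0:
        return 0.0
    # shared control deviate z0 ~ N(0,1): Gauss-Hermite
    x, wx = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    wz = wx / np.sqrt(2 * np.pi)
    # pooled scale W = chi_df / sqrt(df): Gauss-Legendre in quantile space
    u, wu = np.polynomial.legendre.leggauss(_GL_NODES)
    qgrid = 0.5 * (u + 1.0)
    wq = 0.5 * wu
    w_vals = stats.chi.ppf(qgrid, df) / np.sqrt(df)

    s = np.sqrt(1.0 - lambdas**2)
    qw = q * w_vals[:, None, None]            # (W, 1, 1)
    lz = lambdas[None, None, :] * x[None, :, None]  # (1, Z, k)
    upper = (qw - lz) / s[None, None, :]
    lower = (-qw - lz) / s[None, None, :]
    probs = stats.norm.cdf(upper) - stats.norm.cdf(lower)
    inner = probs.prod(axis=2) @ wz            # (W,)
    return float(np.clip(inner @ wq, 0.0, 1.0))


def dunnett_pvalues(
    treatment_groups: Sequence[Sequence[float]],
    control: Sequence[float],
) -> np.ndarray:
    """Two-sided Dunnett p-values for each treatment vs the control.

    Each p-value is P(max_j |T_j| >= |t_i|) under the joint null, i.e. it
    is already adjusted for the family of comparisons.
    """
    control = np.asarray(control, dtype=float)
    groups = [np.asarray(g, dtype=float) for g in treatment_groups]
    if len(groups) < 1:
        raise MultCompError("need at least one treatment group")
    for g in [control, *groups]:
        if len(g) < 3:
            raise MultCompError("each group needs >= 3 observations")
    allg = [control, *groups]
    df = sum(len(g) - 1 for g in allg)
    ss = sum(((g - g.mean()) ** 2).sum() for g in allg)
    if ss <= 0:
        raise MultCompError("zero pooled variance across groups")
    s2 = ss / df
    n0, m0 = len(control), control.mean()
    t_stats = np.array(
        [
            (g.mean() - m0) / np.sqrt(s2 * (1.0 / len(g) + 1.0 / n0))
            for g in groups
        ]
    )
    if len(groups) == 1:
        return np.array([2.0 * stats.t.sf(abs(t_stats[0]), df)])
    lambdas = np.array([np.sqrt(len(g) / (len(g) + n0)) for g in groups])
    return np.array(
        [1.0 - _max_abs_t_cdf(abs(t), lambdas, df) for t in t_stats]
    )
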