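"""Statistical comparisons for replicate reporter scores.

Two procedures cover the comparisons used in this kind of experiment:

* families of unpaired two-tailed t-tests with Holm-Šidák step-down
  adjustment (one family per panel of related comparisons);
* one-way ANOVA with Dunnett's many-to-one comparisons against a shared
  control, with familywise-adjusted two-sided p-values from the
  equicorrelated multivariate-t distribution.

Dunnett probabilities are computed by deterministic quadrature: conditioning
on the control-group variate and the pooled-SD chi variable factorizes the
joint rectangle probability into a product of normal CDFs, which is then
integrated with Gauss-Legendre (over the chi probability scale) and
Gauss-Hermite (over the shared normal variate) rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "ttest_two_sample",
    "holm_sidak_adjust",
    "anova_dunnett",
    "dunnett_critical_value",
    "UndefinedTestError",
]


class UndefinedTestError(ValueError):
    """The test statistic is undefined (too few replicates or zero variance)."""


@dataclass(frozen=True)
class ComparisonResult:
    label: str
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float
    method: str


def ttest_two_sample(
    a,
    b,
    variance_mode: str = "pooled",
) -> tuple[float, float, float]:
    """Unpaired two-tailed t-test; returns (statistic, df, p).

    ``variance_mode='pooled'`` is the classic Student test;
    ``'welch'`` drops the equal-variance assumption.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise UndefinedTestError("each group needs at least 2 replicates")
    if variance_mode not in ("pooled", "welch"):
        raise ValueError(f"unknown variance_mode {variance_mode!r}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise UndefinedTestError("zero variance in both groups")
    res = sps.ttest_ind(a, b, equal_var=(variance_mode == "pooled"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def holm_sidak_adjust(p_values) -> np.ndarray:
    """Holm-Šidák step-down adjusted p-values, in input order.

    Sorted ascending, the i-th smallest raw p becomes
    ``1 - (1 - p_(i)) ** (m - i + 1)``, subject to a running maximum and
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    with np.errstate(divide="ignore"):  # log1p(-1) for raw p == 1 is fine
        _, adj, _, _ = multipletests(p, method="holm-sidak")
    return adj


def _dunnett_acceptance_prob(
    q: np.ndarray | float,
    lambdas: np.ndarray,
    df: int,
    n_chi: int = 96,
    n_z: int = 96,
) -> np.ndarray:
    """P(max_i |T_i| <= q) for equicorrelated Dunnett statistics.

    T_i = D_i / W with D_i = sqrt(1-lambda_i^2) Z_i + lambda_i Z0 standard
    normal (corr lambda_i lambda_j) and df * W^2 ~ chi^2_df. The Z_i
    integrate to a product of normal CDFs conditional on (Z0, W).
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    lam = lambdas[:, None, None]
    s = np.sqrt(1.0 - lambdas**2)[:, None, None]

    # chi variable on the probability scale (Gauss-Legendre on (0,1))
    p_nodes, p_weights = np.polynomial.legendre.leggauss(n_chi)
    p_nodes = 0.5 * (p_nodes + 1.0)
    p_weights = 0.5 * p_weights
    w_nodes = sps.chi.ppf(p_nodes, df) / math.sqrt(df)  # (n_chi,)

    # shared normal variate via Gauss-Hermite
    h_nodes, h_weights = np.polynomial.hermite.hermgauss(n_z)
    z_nodes = math.sqrt(2.0) * h_nodes
    z_weights = h_weights / math.sqrt(math.pi)

    out = np.empty(q.shape)
    zw = z_nodes[None, :], w_nodes[:, None]  # broadcast (n_chi, n_z)
    for idx, qv in np.ndenumerate(q):
        upper = (qv * zw[1] - lam * zw[0]) / s  # (k, n_chi, n_z)
        lower = (-qv * zw[1] - lam * zw[0]) / s
        prod = np.prod(sps.norm.cdf(upper) - sps.norm.cdf(lower), axis=0)
        out[idx] = float(p_weights @ prod @ z_weights)
    return out


def _anova_pool(groups: list[np.ndarray]) -> tuple[float, int]:
    """One-way ANOVA pooled error variance and residual df."""
    n_total = sum(g.size for g in groups)
    df = n_total - len(groups)
    if df <= 0:
        raise UndefinedTestError("no residual degrees of freedom")
    sse = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    mse = sse / df
    if mse == 0:
        raise UndefinedTestError("zero pooled variance across groups")
    return mse, df


def anova_dunnett(
    groups,
    control_index: int = 0,
    labels: list[str] | None = None,
) -> list[ComparisonResult]:
    """Many-to-one comparisons of every group against a shared control.

    Pools variance with one-way ANOVA, forms each group-vs-control t
    statistic, and adjusts two-sided p-values over the family with the
    multivariate-t equicoordinate probability (deterministic quadrature,
    absolute accuracy well under 1e-4).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least a control and one treatment group")
    if not 0 <= control_index < len(groups):
        raise ValueError(f"control_index {control_index} out of range")
    if any(g.size < 2 for g in groups):
        raise UndefinedTestError("each group needs at least 2 replicates")
    mse, df = _anova_pool(groups)
    control = groups[control_index]
    others = [(i, g) for i, g in enumerate(groups) if i != control_index]

    n0 = control.size
    n_i = np.array([g.size for _, g in others], dtype=float)
    lambdas = np.sqrt(n_i / (n_i + n0))
    t_obs = np.array(
        [
            (g.mean() - control.mean()) / math.sqrt(mse * (1.0 / g.size + 1.0 / n0))
            for _, g in others
        ]
    )
    p_adj = 1.0 - _dunnett_acceptance_prob(np.abs(t_obs), lambdas, df)
    results = []
    for k, (i, _) in enumerate(others):
        label = labels[i] if labels else f"group{i}"
        p_raw = 2.0 * sps.t.sf(abs(t_obs[k]), df)
        results.append(
            ComparisonResult(
                label=label,
                statistic=float(t_obs[k]),
                df=float(df),
                p_raw=float(p_raw),
                p_adjusted=float(min(max(p_adj[k], p_raw), 1.0)),
                method="anova_dunnett",
            )
        )
    return results


def dunnett_critical_value(
    alpha: float,
    k: int,
    df: int,
    n_per_group: int | None = None,
    n_control: int | None = None,
) -> float:
    """Two-sided Dunnett critical value q with P(max|T_i| > q) = alpha.

    Balanced designs (the default) use correlation 1/2 between comparisons.
    """
    if n_per_group is None or n_control is None:
        lambdas = np.full(k, math.sqrt(0.5))
    else:
        lambdas = np.full(k, math.sqrt(n_per_group / (n_per_group + n_control)))

    def fwer(q: float) -> float:
        return 1.0 - float(_dunnett_acceptance_prob(q, lambdas, df)[0]) - alpha

    return float(optimize.brentq(fwer, 0.5, 50.0, xtol=1e-6))


def ttest_family(
    pairs,
    labels: list[str] | None = None,
    variance_mode: str = "pooled",
) -> list[ComparisonResult]:
    """A family of unpaired t-tests with Holm-Šidák adjustment.

    ``pairs`` is a sequence of (a, b) replicate-value pairs forming one
    multiplicity family (e.g. one comparison per pathway within a figure
    panel).
    """
    stats_df_p = [ttest_two_sample(a, b, variance_mode) for a, b in pairs]
    p_adj = holm_sidak_adjust([p for _, _, p in stats_df_p])
    return [
        ComparisonResult(
            label=labels[i] if labels else f"comparison{i}",
            statistic=t,
            df=df,
            p_raw=p,
            p_adjusted=float(p_adj[i]),
            method="t_holm_sidak",
        )
        for i, (t, df, p) in enumerate(stats_df_p)
    ]
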