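"""Trait screening and many-to-one comparisons.

Each trait (log2 relative abundance) is screened by a one-way fixed-effects
ANOVA with pedigree (the NILs and the recurrent parent) as the factor,
corrected across traits by Benjamini-Hochberg.  Retained traits are then
compared line-by-line against the control with Dunnett's many-to-one test,
whose family-wise adjustment integrates the joint distribution of the
contrast statistics: with group sizes n_i and control size n_0 the t
statistics follow a multivariate t with df = N - k and correlation
rho_ij = lambda_i lambda_j, lambda_i = sqrt(n_i / (n_i + n_0)).

The adjusted p-value P(max_i |T_i| >= |t_j|) is evaluated by deterministic
Gauss quadrature over the one-factor representation
T_i = (lambda_i Z0 + sqrt(1 - lambda_i^2) Z_i) / W,  W^2 ~ chi^2_df / df:
conditioning on (Z0, W) makes the coordinates independent, so the orthant
probability is a product of normal CDF differences integrated over
Gauss-Hermite (Z0) x Gauss-Legendre (W) nodes.  Accuracy is well below the
1e-3 working tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import roots_hermitenorm, roots_legendre
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class AnovaResult:
    trait: str
    F: float
    df_between: int
    df_within: int
    p_raw: float
    p_adj: float = float("nan")


@dataclass(frozen=True)
class DunnettResult:
    trait: str
    control: str
    estimates: dict[str, float]     # line -> log2 mean difference vs control
    p_adjusted: dict[str, float]    # line -> family-wise adjusted p
    alpha: float = DEFAULT_ALPHA

    def significant(self, line: str) -> bool:
        return self.p_adjusted[line] < self.alpha


@dataclass(frozen=True)
class SignificancePattern:
    """Per-trait Dunnett outcome coded line -> {+1, -1, 0}."""

    trait: str
    entries: dict[str, int]
    source: str = "computed"  # or "encoded" when read from a printed table

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.entries.items() if v not in (-1, 0, 1)}
        if bad:
            raise ValueError(f"pattern entries must be in {{-1,0,1}}: {bad}")

    @property
    def is_null(self) -> bool:
        return all(v == 0 for v in self.entries.values())

    @property
    def signs(self) -> set[int]:
        return {v for v in self.entries.values() if v != 0}


def _groups(log_values: pd.DataFrame, sample_line: pd.Series) -> dict[str, np.ndarray]:
    sample_line = sample_line.reindex(log_values.index)
    return {
        str(line): np.flatnonzero((sample_line == line).to_numpy())
        for line in pd.unique(sample_line)
    }


def anova_per_trait(log_values: pd.DataFrame, sample_line: pd.Series) -> list[AnovaResult]:
    """One-way fixed-effects ANOVA per trait column.

    The degenerate all-identical trait (zero between- and within-group
    variance) is reported as F = 0, p = 1: an uninformative trait.
    """
    groups = _groups(log_values, sample_line)
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 pedigree groups")
    for line, idx in groups.items():
        if idx.size < 2:
            raise ValueError(f"line {line!r} has fewer than 2 samples")
    k = len(groups)
    n_total = sum(idx.size for idx in groups.values())
    results = []
    for trait in log_values.columns:
        y = log_values[trait].to_numpy(dtype=float)
        samples = [y[idx] for idx in groups.values()]
        if np.ptp(y) == 0.0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = stats.f_oneway(*samples)
            if not np.isfinite(f_stat):  # zero within-group variance
                f_stat, p = np.inf, 0.0
        results.append(
            AnovaResult(
                trait=str(trait), F=float(f_stat),
                df_between=k - 1, df_within=n_total - k,
                p_raw=float(p),
            )
        )
    return results


def bh_adjust(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_bh(results: list[AnovaResult]) -> list[AnovaResult]:
    adj = bh_adjust([r.p_raw for r in results])
    return [
        AnovaResult(r.trait, r.F, r.df_between, r.df_within, r.p_raw, float(a))
        for r, a in zip(results, adj)
    ]


def screen_traits(results: list[AnovaResult], alpha: float = DEFAULT_ALPHA) -> list[str]:
    """Traits whose BH-adjusted ANOVA p is strictly below ``alpha``."""
    adjusted = [r if np.isfinite(r.p_adj) else None for r in results]
    if any(r is None for r in adjusted):
        results = attach_bh(results)
    return [r.trait for r in results if r.p_adj < alpha]


class _DunnettIntegrator:
    """Quadrature grid for the equicorrelated multivariate-t tail probability."""

    def __init__(self, lambdas: np.ndarray, df: int,
                 n_hermite: int = 80, n_legendre: int = 48):
        self.lambdas = np.asarray(lambdas, dtype=float)
        self.df = int(df)
        z_nodes, z_w = roots_hermitenorm(n_hermite)
        self.z = z_nodes
        self.zw = z_w / np.sqrt(2.0 * np.pi)
        u, uw = roots_legendre(n_legendre)
        u01 = 0.5 * (u + 1.0)
        self.w = np.sqrt(stats.chi2.ppf(u01, self.df) / self.df)
        self.ww = 0.5 * uw
        self.s = np.sqrt(1.0 - self.lambdas**2)

    def max_abs_cdf(self, c) -> np.ndarray:
        """P(max_i |T_i| < c), vectorised over an array of thresholds."""
        c = np.atleast_1d(np.asarray(c, dtype=float))
        cw = c[:, None] * self.w[None, :]                    # (nc, nw)
        lz = self.lambdas[:, None] * self.z[None, :]         # (k, nz)
        # upper/lower conditional bounds: (nc, nw, k, nz)
        upper = (cw[:, :, None, None] - lz[None, None]) / self.s[None, None, :, None]
        lower = (-cw[:, :, None, None] - lz[None, None]) / self.s[None, None, :, None]
        probs = stats.norm.cdf(upper) - stats.norm.cdf(lower)
        prod = np.prod(probs, axis=2)                        # over contrasts
        inner = prod @ self.zw                               # integrate Z0
        return np.clip(inner @ self.ww, 0.0, 1.0)            # integrate W

    def adjusted_p(self, tstats) -> np.ndarray:
        return 1.0 - self.max_abs_cdf(np.abs(np.asarray(tstats, dtype=float)))

    def critical_value(self, alpha: float = DEFAULT_ALPHA) -> float:
        from scipy.optimize import brentq

        return float(
            brentq(lambda c: self.max_abs_cdf(c)[0] - (1.0 - alpha), 1e-6, 50.0)
        )


def dunnett_many_to_one(
    log_values: pd.DataFrame,
    sample_line: pd.Series,
    control: str = "PS",
    alpha: float = DEFAULT_ALPHA,
) -> list[DunnettResult]:
    """Two-sided Dunnett comparisons of every line against the control.

    Uses the pooled within-group variance per trait; the family-wise
    adjustment is shared across traits because it depends only on the group
    sizes and residual degrees of freedom.
    """
    groups = _groups(log_values, sample_line)
    if control not in groups:
        raise ValueError(f"control line {control!r} not present")
    if len(groups) < 2:
        raise ValueError("need at least one non-control line")
    others = [g for g in groups if g != control]
    n0 = groups[control].size
    ns = np.array([groups[g].size for g in others])
    n_total = n0 + ns.sum()
    df = n_total - len(groups)
    if df < 1:
        raise ValueError("no residual degrees of freedom")
    lambdas = np.sqrt(ns / (ns + n0))
    integrator = _DunnettIntegrator(lambdas, df)

    y = log_values.to_numpy(dtype=float)
    mean_c = y[groups[control]].mean(axis=0)
    means = np.stack([y[groups[g]].mean(axis=0) for g in others])  # (k-1, T)
    ss_within = sum(
        ((y[idx] - y[idx].mean(axis=0)) ** 2).sum(axis=0) for idx in groups.values()
    )
    s2 = ss_within / df
    se = np.sqrt(s2[None, :] * (1.0 / ns + 1.0 / n0)[:, None])
    diffs = means - mean_c[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstats = np.where(se > 0, diffs / se, 0.0)
    p_adj = integrator.adjusted_p(tstats.ravel()).reshape(tstats.shape)

    results = []
    for j, trait in enumerate(log_values.columns):
        results.append(
            DunnettResult(
                trait=str(trait),
                control=control,
                estimates={g: float(diffs[i, j]) for i, g in enumerate(others)},
                p_adjusted={g: float(p_adj[i, j]) for i, g in enumerate(others)},
                alpha=alpha,
            )
        )
    return results


def significance_patterns(
    dunnett_results: list[DunnettResult],
) -> list[SignificancePattern]:
    """Code each Dunnett result as line -> {+1, -1, 0}.

    The sign is the sign of the log2 mean difference against the control
    (log2 is monotone, so it matches the raw-scale direction).
    """
    patterns = []
    for res in dunnett_results:
        entries = {}
        for line, est in res.estimates.items():
            if res.significant(line) and est != 0.0:
                entries[line] = 1 if est > 0 else -1
            else:
                entries[line] = 0
        patterns.append(SignificancePattern(res.trait, entries, source="computed"))
    return patterns


def flag_outliers(values: pd.DataFrame, sample_line: pd.Series,
                  whisker: float = 1.5) -> pd.DataFrame:
    """Box-whisker outlier report (per line and trait); never removes data."""
    sample_line = sample_line.reindex(values.index)
    flags = pd.DataFrame(False, index=values.index, columns=values.columns)
    for _, idx in values.groupby(sample_line).groups.items():
        sub = values.loc[idx]
        q1, q3 = sub.quantile(0.25), sub.quantile(0.75)
        iqr = q3 - q1
        lo, hi = q1 - whisker * iqr, q3 + whisker * iqr
        flags.loc[idx] = (sub < lo) | (sub > hi)
    return flags
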