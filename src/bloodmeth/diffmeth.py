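"""Probe-wise differential methylation: one-way group fit, empirical-Bayes
moderated t contrasts, and Benjamini-Hochberg correction.

The model is a one-way layout of M-values on population.  Per probe, the
pooled residual variance s^2 with d = N - G degrees of freedom is shrunk
toward an ensemble prior (d0, s0^2) estimated from all probes by the
method of moments on log s^2 (digamma/trigamma relations).  The moderated
t for a contrast (A - B) uses the posterior variance

    s2_post = (d0 * s0^2 + d * s^2) / (d0 + d)

and is referred to a t distribution with d0 + d degrees of freedom.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datamodel import MValueMatrix, SampleSheet

__all__ = [
    "GroupFit",
    "ModerationParams",
    "fit_groups",
    "estimate_moderation",
    "posterior_variance",
    "moderated_contrast",
    "bh_adjust",
    "all_pairwise",
]


@dataclass
class GroupFit:
    """Per-probe group means and pooled residual variance of a one-way fit."""

    probe_ids: np.ndarray
    groups: tuple
    means: np.ndarray  # (n_probes, n_groups)
    s2: np.ndarray  # (n_probes,)
    df: int
    n_per_group: dict

    def group_mean(self, group: str) -> np.ndarray:
        return self.means[:, self.groups.index(group)]


@dataclass
class ModerationParams:
    """Empirical-Bayes prior: d0 prior degrees of freedom (may be inf),
    s0^2 prior variance."""

    d0: float
    s0_2: float


def fit_groups(m: MValueMatrix, sheet: SampleSheet, groups=None) -> GroupFit:
    """One-way fit of M on population: group means and pooled residual
    variance with df = N - G.

    Every included group needs >= 2 samples (the residual variance is
    otherwise undefined), and >= 2 groups are required.
    """
    if groups is None:
        groups = sheet.population_set
    groups = tuple(groups)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    cols = {g: [list(m.sample_ids).index(s) for s in sheet.samples_of(g)] for g in groups}
    for g, idx in cols.items():
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has {len(idx)} sample(s); need >= 2")
    n_total = sum(len(idx) for idx in cols.values())
    df = n_total - len(groups)

    means = np.empty((m.values.shape[0], len(groups)))
    rss = np.zeros(m.values.shape[0])
    for k, g in enumerate(groups):
        sub = m.values[:, cols[g]]
        mu = sub.mean(axis=1)
        means[:, k] = mu
        rss += ((sub - mu[:, None]) ** 2).sum(axis=1)
    s2 = rss / df
    return GroupFit(
        m.probe_ids, groups, means, s2, df, {g: len(idx) for g, idx in cols.items()}
    )


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 (Newton, as in the moderated-t
    literature)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y  # starting value; exact as y -> 0
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif / x) < 1e-10):
            break
    return x


def estimate_moderation(s2: np.ndarray, df: int, min_positive: int = 10) -> ModerationParams:
    """Estimate the variance prior (d0, s0^2) from the ensemble of probe
    variances.

    Method of moments on z = log(s^2): with s^2 ~ s0^2 * F(d, d0),
    E z = log s0^2 + psi(d/2) - log(d/2) - psi(d0/2) + log(d0/2) and
    Var z = psi'(d/2) + psi'(d0/2).  When the observed variance of z does
    not exceed psi'(d/2), there is no evidence of between-probe variance
    heterogeneity and d0 = inf is returned.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if len(pos) == 0:
        warnings.warn("all residual variances are zero; returning d0=inf fallback", stacklevel=2)
        return ModerationParams(np.inf, np.finfo(float).tiny)
    if len(pos) < min_positive:
        raise ValueError(f"need >= {min_positive} probes with positive variance")
    z = np.log(pos)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    if evar < 1e-15:
        # degenerate: identical variances carry no sampling scatter, so no
        # finite-df bias correction applies — the common value is the prior
        return ModerationParams(np.inf, float(np.exp(z.mean())))
    rhs = evar - special.polygamma(1, df / 2.0)
    if rhs <= 0:
        return ModerationParams(np.inf, float(np.exp(emean)))
    half_d0 = float(_trigamma_inverse(np.array(rhs)))
    d0 = 2.0 * half_d0
    s0_2 = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    return ModerationParams(d0, s0_2)


def posterior_variance(s2: np.ndarray, df: int, mod: ModerationParams) -> np.ndarray:
    """Shrunken variance (d0*s0^2 + d*s^2)/(d0 + d); s0^2 when d0 is infinite,
    s^2 in the d0 -> 0 limit."""
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(mod.d0):
        return np.full_like(s2, mod.s0_2)
    if mod.d0 == 0:
        return s2.copy()
    return (mod.d0 * mod.s0_2 + df * s2) / (mod.d0 + df)


def moderated_contrast(fit: GroupFit, mod: ModerationParams, a: str, b: str) -> pd.DataFrame:
    """Moderated t-test of the contrast mean(A) - mean(B) for every probe.

    Returns a DataFrame with delta_m (the log2-fold-change in M units),
    t_mod, two-sided p, BH q and a significance flag (filled by the caller
    or by :func:`all_pairwise`; here q is per-contrast BH at alpha left to
    the caller).
    """
    if a == b:
        raise ValueError("contrast requires two distinct groups")
    na, nb = fit.n_per_group[a], fit.n_per_group[b]
    delta = fit.group_mean(a) - fit.group_mean(b)
    s2_post = posterior_variance(fit.s2, fit.df, mod)
    se2 = s2_post * (1.0 / na + 1.0 / nb)
    df_total = mod.d0 + fit.df

    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(se2)
    # zero posterior variance: infinite t unless the difference is also zero
    zero_se = se2 == 0
    t = np.where(zero_se & (delta == 0), 0.0, t)
    t = np.where(zero_se & (delta > 0), np.inf, t)
    t = np.where(zero_se & (delta < 0), -np.inf, t)

    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(delta == 0, 1.0, p)
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "probe_id": fit.probe_ids,
            "contrast_a": a,
            "contrast_b": b,
            "delta_m": delta,
            "t_mod": t,
            "p": p,
            "q": q,
        }
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def all_pairwise(
    m: MValueMatrix,
    sheet: SampleSheet,
    alpha: float = 0.01,
    mod: ModerationParams | None = None,
    global_adjust: bool = False,
):
    """Significant-probe counts for every pair of populations.

    Returns (counts DataFrame, dict of per-contrast result frames).  BH is
    applied within each pairwise contrast separately by default (each pair's
    counts are then comparable to a per-contrast threshold); ``global_adjust``
    pools all contrasts into one BH pass instead.
    """
    groups = sheet.population_set
    if len(groups) < 2:
        raise ValueError("need at least 2 populations")
    fit = fit_groups(m, sheet, groups)
    if mod is None:
        mod = estimate_moderation(fit.s2, fit.df)

    results = {}
    for a, b in itertools.combinations(groups, 2):
        results[(a, b)] = moderated_contrast(fit, mod, a, b)
    if global_adjust:
        all_p = np.concatenate([r["p"].to_numpy() for r in results.values()])
        all_q = bh_adjust(all_p)
        i = 0
        for r in results.values():
            r["q"] = all_q[i : i + len(r)]
            i += len(r)
    counts = pd.DataFrame(0, index=list(groups), columns=list(groups))
    for (a, b), r in results.items():
        r["significant"] = r["q"] < alpha
        n_sig = int(r["significant"].sum())
        counts.loc[a, b] = n_sig
        counts.loc[b, a] = n_sig
    return counts, results
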