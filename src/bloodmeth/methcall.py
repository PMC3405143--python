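"""Three-state methylation calling via a two-component gamma mixture on
M-values.

Per sample, the M-value distribution is modelled as a mixture of two gamma
components reflected toward each other:

    f(m) = pi_u * Gamma(anchor_u - m; k_u, theta_u)
         + (1 - pi_u) * Gamma(m - anchor_m; k_m, theta_m)

The "unmethylated" component hangs from a right anchor just above the data
maximum (its density lives on m < anchor_u) and, after initialization from
the sign of M, captures the low-M mode; the "methylated" component rises
from a left anchor just below the minimum and captures the high-M mode.
Because both anchors are data-driven, the fit — and hence the calls — is
equivariant under adding a constant to all M-values.

The fit is by EM: the E-step computes posterior responsibilities, the
M-step does weighted gamma maximum likelihood (Newton on the shape through
the digamma function, closed-form scale).  The posterior probability of the
methylated component, thresholded at tau, defines the three calls
unmethylated / marginal / methylated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "CALL_STATES",
    "GammaMixtureFit",
    "fit_gamma_mixture",
    "posterior_methylated",
    "call_from_posterior",
    "call_matrix",
    "consensus_call",
    "consensus_calls",
    "discordance_filter",
    "call_distribution",
]

CALL_STATES = ("Unmethylated", "Marginal", "Methylated")

_DENSITY_FLOOR = 1e-300
_PI_PIN = 1e-6


@dataclass
class GammaMixtureFit:
    """Fitted two-component gamma mixture for one sample."""

    anchor_u: float
    anchor_m: float
    shape_u: float
    scale_u: float
    shape_m: float
    scale_m: float
    pi_u: float
    loglik_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = False
    #: True when the top-anchored component captured the high-M data mode
    #: (components hugging their own anchors) rather than reaching across;
    #: the calling layer uses this to map components to methylation states.
    inverted: bool = False

    def density_u(self, m):
        x = self.anchor_u - np.asarray(m, dtype=float)
        d = np.where(x > 0, stats.gamma.pdf(np.maximum(x, 0), self.shape_u, scale=self.scale_u), 0.0)
        return np.maximum(d, _DENSITY_FLOOR)

    def density_m(self, m):
        x = np.asarray(m, dtype=float) - self.anchor_m
        d = np.where(x > 0, stats.gamma.pdf(np.maximum(x, 0), self.shape_m, scale=self.scale_m), 0.0)
        return np.maximum(d, _DENSITY_FLOOR)

    def loglik(self, m):
        mix = self.pi_u * self.density_u(m) + (1 - self.pi_u) * self.density_m(m)
        return float(np.log(np.maximum(mix, _DENSITY_FLOOR)).sum())

    def p_methylated(self, m):
        """Posterior probability of the high-methylation state.

        The component whose posterior mass sits at higher M represents the
        methylated state; for an inverted fit (components hugging their own
        anchors) that is the top-anchored component, otherwise the
        bottom-anchored one.
        """
        p = posterior_methylated(self, m)
        return 1.0 - p if self.inverted else p


def _weighted_gamma_mle(x: np.ndarray, w: np.ndarray, max_newton: int = 40):
    """Weighted gamma MLE: Newton on log-shape via digamma, closed-form scale.

    Solves log(k) - psi(k) = log(mean_w x) - mean_w(log x).
    """
    wsum = w.sum()
    xbar = float((w * x).sum() / wsum)
    logbar = float((w * np.log(x)).sum() / wsum)
    s = np.log(xbar) - logbar  # >= 0 by Jensen
    if s <= 1e-12:
        # essentially degenerate (all mass at one point): very peaked gamma
        k = 1e6
        return k, xbar / k
    # Minka's closed-form start
    k = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(max_newton):
        g = np.log(k) - special.digamma(k) - s
        dg = 1.0 / k - special.polygamma(1, k)
        step = g / dg
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        if abs(k_new - k) < 1e-10 * k:
            k = k_new
            break
        k = k_new
    k = float(np.clip(k, 1e-8, 1e8))
    return k, xbar / k


def fit_gamma_mixture(
    m,
    init: dict | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    anchor_eps: float = 0.1,
    restarts: int = 3,
    seed: int = 0,
) -> GammaMixtureFit:
    """EM fit of the two-component reflected gamma mixture to M-values.

    ``init`` may override ``anchor_u``/``anchor_m``, the initial
    responsibilities split point (``split``, default 0) and the component
    ``orientation``: "low" (default) starts the top-anchored component on the
    low-M side of the split — the state-consistent geometry in which the
    unmethylated component describes the low-M mode; "high" starts it on the
    high-M side (components hugging their own anchors); "auto" tries both and
    keeps the better likelihood.  The likelihood surface has near-mirror
    basins under this choice, so the default pins the interpretable one
    rather than letting label switching decide.  Randomized restarts
    (responsibilities perturbed, seeded) guard against poor local optima
    within the chosen basin; the best log-likelihood wins.  Non-convergence
    at ``max_iter`` returns the best fit with ``converged=False``.
    """
    m = np.asarray(m, dtype=float).ravel()
    if len(m) < 100:
        raise ValueError("need at least 100 values to fit the mixture")
    init = init or {}
    anchor_u = float(init.get("anchor_u", m.max() + anchor_eps))
    anchor_m = float(init.get("anchor_m", m.min() - anchor_eps))
    # the split defaults to the data midrange rather than a fixed 0 so the
    # whole fit is equivariant under adding a constant to all M-values
    split = float(init.get("split", 0.5 * (m.min() + m.max())))
    if anchor_u <= m.max() or anchor_m >= m.min():
        raise ValueError("anchors must lie strictly outside the data range")

    x_u = anchor_u - m  # > 0
    x_m = m - anchor_m  # > 0

    orientation = init.get("orientation", "low")
    if orientation not in ("low", "high", "auto"):
        raise ValueError(f"unknown orientation {orientation!r}")
    rng = np.random.default_rng(seed)
    base_low = np.where(m < split, 0.9, 0.1)
    bases = {"low": [base_low], "high": [1.0 - base_low], "auto": [base_low, 1.0 - base_low]}[orientation]
    inits = list(bases)
    for base in bases:
        for _ in range(max(restarts - 1, 0)):
            inits.append(np.clip(base + rng.normal(0, 0.2, size=len(m)), 0.02, 0.98))

    best = None
    for r_u in inits:
        fit = _em_run(m, x_u, x_m, anchor_u, anchor_m, r_u, tol, max_iter)
        if best is None or fit.loglik_trace[-1] > best.loglik_trace[-1]:
            best = fit

    # orientation: which component owns the higher-M data mass
    du = best.pi_u * best.density_u(m)
    dm = (1 - best.pi_u) * best.density_m(m)
    r_u = du / np.maximum(du + dm, _DENSITY_FLOOR)
    mean_u = float((r_u * m).sum() / max(r_u.sum(), 1e-12))
    mean_m = float(((1 - r_u) * m).sum() / max((1 - r_u).sum(), 1e-12))
    best.inverted = mean_u > mean_m
    return best


def _em_run(m, x_u, x_m, anchor_u, anchor_m, r_u, tol, max_iter) -> GammaMixtureFit:
    trace = []
    pi_u = float(np.clip(r_u.mean(), _PI_PIN, 1 - _PI_PIN))
    shape_u = scale_u = shape_m = scale_m = None
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        # M-step
        pi_u = float(np.clip(r_u.mean(), _PI_PIN, 1 - _PI_PIN))
        w_u = np.maximum(r_u, 1e-12)
        w_m = np.maximum(1.0 - r_u, 1e-12)
        shape_u, scale_u = _weighted_gamma_mle(x_u, w_u)
        shape_m, scale_m = _weighted_gamma_mle(x_m, w_m)
        fit = GammaMixtureFit(anchor_u, anchor_m, shape_u, scale_u, shape_m, scale_m, pi_u)
        # E-step
        du = pi_u * fit.density_u(m)
        dm = (1 - pi_u) * fit.density_m(m)
        total = du + dm
        ll = float(np.log(np.maximum(total, _DENSITY_FLOOR)).sum())
        trace.append(ll)
        r_u = du / np.maximum(total, _DENSITY_FLOOR)
        if prev > -np.inf and abs(ll - prev) < tol * (abs(prev) + 1e-12):
            converged = True
            break
        prev = ll
    if pi_u in (_PI_PIN, 1 - _PI_PIN):
        warnings.warn("mixing proportion pinned at boundary (one-sided data)", stacklevel=3)
    if not converged:
        warnings.warn("EM did not converge within max_iter", stacklevel=3)
    return GammaMixtureFit(
        anchor_u, anchor_m, shape_u, scale_u, shape_m, scale_m, pi_u,
        np.asarray(trace), converged,
    )


def posterior_methylated(fit: GammaMixtureFit, m):
    """P(methylated | m) = (1-pi_u) f_m(m) / [pi_u f_u(m) + (1-pi_u) f_m(m)]."""
    du = fit.pi_u * fit.density_u(m)
    dm = (1 - fit.pi_u) * fit.density_m(m)
    return dm / (du + dm)


def call_from_posterior(p_meth, tau: float = 0.9):
    """Three-state call: Methylated if p >= tau, Unmethylated if p <= 1 - tau,
    otherwise Marginal (the "balanced" state)."""
    if not 0.5 < tau < 1:
        raise ValueError("tau must lie in (0.5, 1)")
    p = np.asarray(p_meth, dtype=float)
    calls = np.full(p.shape, "Marginal", dtype=object)
    calls[p >= tau] = "Methylated"
    calls[p <= 1 - tau] = "Unmethylated"
    if p.ndim == 0:
        return str(calls[()])
    return calls


def call_matrix(m_matrix, tau: float = 0.9, fit_kwargs: dict | None = None):
    """Fit the mixture per sample and call every probe.

    Returns (calls DataFrame probes x samples, posteriors DataFrame,
    dict of per-sample fits).
    """
    fit_kwargs = fit_kwargs or {}
    fits = {}
    calls = {}
    posts = {}
    for sid in m_matrix.sample_ids:
        col = m_matrix.column(sid)
        fit = fit_gamma_mixture(col, **fit_kwargs)
        p = fit.p_methylated(col)
        fits[sid] = fit
        posts[sid] = p
        calls[sid] = call_from_posterior(p, tau)
    idx = pd.Index(m_matrix.probe_ids, name="probe_id")
    return (
        pd.DataFrame(calls, index=idx),
        pd.DataFrame(posts, index=idx),
        fits,
    )


def consensus_call(calls) -> str:
    """Strict-majority consensus over per-donor calls; any tie for the
    plurality yields Marginal."""
    calls = list(calls)
    if not calls:
        raise ValueError("need at least one call")
    counts = {}
    for c in calls:
        counts[c] = counts.get(c, 0) + 1
    best = max(counts.values())
    winners = [c for c, n in counts.items() if n == best]
    return winners[0] if len(winners) == 1 else "Marginal"


def consensus_calls(calls_df: pd.DataFrame, sheet) -> pd.DataFrame:
    """Per-population consensus call matrix (probes x populations)."""
    out = {}
    for pop in sheet.population_set:
        cols = sheet.samples_of(pop)
        sub = calls_df[cols].to_numpy()
        out[pop] = [consensus_call(row) for row in sub]
    return pd.DataFrame(out, index=calls_df.index)


def discordance_filter(results: pd.DataFrame, calls_a: pd.Series, calls_b: pd.Series) -> pd.DataFrame:
    """Keep significant probes whose consensus calls differ between the two
    compared populations; significant probes sharing the same call are
    removed.

    ``results`` must carry probe_id and a ``significant`` flag; the returned
    frame is the kept subset annotated with ``call_a``/``call_b``.
    """
    sig = results[results["significant"]].copy()
    missing = [p for p in sig["probe_id"] if p not in calls_a.index or p not in calls_b.index]
    if missing:
        raise KeyError(f"missing consensus call for probe(s): {missing[:5]}")
    sig["call_a"] = calls_a.loc[sig["probe_id"]].to_numpy()
    sig["call_b"] = calls_b.loc[sig["probe_id"]].to_numpy()
    return sig[sig["call_a"] != sig["call_b"]].reset_index(drop=True)


def call_distribution(filtered: pd.DataFrame, call_column: str = "call_a") -> dict:
    """Percentage of filtered probes in each call state for one population.

    Returns {state: percentage}; percentages sum to 100 within rounding.
    An empty input yields zeros with a warning.
    """
    if len(filtered) == 0:
        warnings.warn("empty filtered set; call distribution is all zero", stacklevel=2)
        return {s: 0.0 for s in CALL_STATES}
    counts = filtered[call_column].value_counts()
    return {s: 100.0 * counts.get(s, 0) / len(filtered) for s in CALL_STATES}
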