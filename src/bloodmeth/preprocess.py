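"""Two-channel intensity preprocessing into M-values.

Pipeline order: background subtraction -> color-channel bias adjustment ->
quantile normalization of the stacked (meth over unmeth) intensity matrix ->
log2-ratio M computation.  Each stage can be switched off individually.

The M-value is M = log2((meth + offset) / (unmeth + offset)); M = 0 means the
methylated and unmethylated signals balance (a half-methylated CpG), positive
M means more methylated than unmethylated.  Beta = 2^M / (2^M + 1) is the
methylated fraction; the two scales are monotone transforms of each other.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import DataValidationError, MValueMatrix, MethylationDataset

log = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "compute_m",
    "m_to_beta",
    "beta_to_m",
    "subtract_background",
    "adjust_color_bias",
    "quantile_normalize",
    "preprocess_pipeline",
]

#: clamp bound for beta -> M at beta in {0, 1}; |M| beyond array dynamic range
M_MAX_DEFAULT = 15.0


@dataclass
class PreprocessConfig:
    """Knobs of the preprocessing pipeline.

    m_offset: constant added to both channels before the log ratio.  It keeps
        the ratio finite at zero intensity and bounds the M dynamic range;
        the default of 100 (the convention also used for beta values)
        prevents background-floored intensities from producing extreme
        log-ratios that would distort the downstream mixture calling.
    background_quantile: per-sample, per-channel quantile subtracted as
        background; 0 disables subtraction.
    color_reference: distribution the Red-channel probes are quantile-mapped
        onto ("Grn", "Red", or "midpoint" of the two).
    """

    m_offset: float = 100.0
    background_quantile: float = 0.05
    color_reference: str = "Grn"
    quantile_target: str = "mean_of_order_statistics"
    do_background: bool = True
    do_color: bool = True
    do_quantile: bool = True

    def __post_init__(self):
        if not self.m_offset > 0:
            raise ValueError("m_offset must be > 0")
        if not 0 <= self.background_quantile < 0.5:
            raise ValueError("background_quantile must be in [0, 0.5)")
        if self.color_reference not in ("Grn", "Red", "midpoint"):
            raise ValueError(f"unknown color_reference {self.color_reference!r}")
        if self.quantile_target != "mean_of_order_statistics":
            raise ValueError("only mean_of_order_statistics is supported")


def compute_m(meth, unmeth, m_offset: float = 1.0):
    """M = log2((meth + offset)/(unmeth + offset)).

    Strictly increasing in meth and strictly decreasing in unmeth; the offset
    guarantees a finite value at zero intensity.
    """
    meth = np.asarray(meth, dtype=float)
    unmeth = np.asarray(unmeth, dtype=float)
    if m_offset <= 0:
        raise ValueError("m_offset must be > 0")
    return np.log2(meth + m_offset) - np.log2(unmeth + m_offset)


def m_to_beta(m):
    """beta = 2^M / (2^M + 1), the methylated fraction."""
    m = np.asarray(m, dtype=float)
    # logistic in base-2 log-odds; stable for large |M|
    return 0.5 * (1.0 + np.tanh(0.5 * np.log(2.0) * m))


def beta_to_m(beta, m_max: float = M_MAX_DEFAULT):
    """M = log2(beta / (1 - beta)); beta in {0,1} clamps to +/- m_max.

    Returns (m, clamped) where clamped flags values at the clamp bound.
    """
    beta = np.asarray(beta, dtype=float)
    if ((beta < 0) | (beta > 1)).any():
        raise ValueError("beta must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        m = np.log2(beta) - np.log2(1.0 - beta)
    clamped = ~np.isfinite(m)
    m = np.clip(m, -m_max, m_max)
    if clamped.any():
        warnings.warn("beta values at 0 or 1 clamped to +/-m_max", stacklevel=2)
    if np.ndim(beta) == 0:
        return float(m), bool(clamped)
    return m, clamped


def subtract_background(dataset: MethylationDataset, background_quantile: float = 0.05):
    """Subtract a per-sample, per-channel background estimate.

    For each sample the ``background_quantile``-th quantile of that signal
    channel (methylated and unmethylated matrices treated separately) is
    subtracted; results are clipped at a floor of 1 intensity unit.  A
    quantile of 0 leaves the data unchanged apart from the floor.
    """
    out = dataset.copy()
    for mat in (out.meth, out.unmeth):
        if background_quantile > 0:
            bg = np.quantile(mat, background_quantile, axis=0, keepdims=True)
            mat -= bg
        np.clip(mat, 1.0, None, out=mat)
    return out


def _quantile_map(values: np.ndarray, source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Map ``values`` through the empirical quantile function source->target."""
    order = np.sort(source)
    tgt = np.sort(target)
    # fractional ranks of values within the source distribution
    ranks = np.searchsorted(order, values, side="left").astype(float)
    ranks += 0.5 * (
        np.searchsorted(order, values, side="right") - ranks
    )  # midpoint for ties
    q = np.clip(ranks / max(len(order) - 1, 1), 0, 1)
    grid = np.linspace(0, 1, len(tgt))
    return np.interp(q, grid, tgt)


def adjust_color_bias(dataset: MethylationDataset, color_reference: str = "Grn"):
    """Quantile-map Red-channel probe intensities onto a reference distribution.

    Within each sample, the pooled (meth + unmeth) intensities of Red-channel
    probes are mapped onto the reference distribution: the Grn probes' pooled
    intensities, the Red probes' own (a no-op), or the arithmetic midpoint of
    the two channels' order statistics ("midpoint", in which case Grn probes
    are mapped too).  Rank order within each channel is preserved.  Probes
    labelled "Both" are untouched.  A channel with fewer than 2 probes is
    skipped with a warning.
    """
    if color_reference not in ("Grn", "Red", "midpoint"):
        raise ValueError(f"unknown color_reference {color_reference!r}")
    out = dataset.copy()
    grn = np.asarray(out.channel == "Grn")
    red = np.asarray(out.channel == "Red")
    if grn.sum() < 2 or red.sum() < 2:
        warnings.warn("a color channel has <2 probes; color adjustment skipped", stacklevel=2)
        return out

    n_g, n_r = int(grn.sum()), int(red.sum())
    for j in range(out.n_samples):
        g_pool = np.concatenate([out.meth[grn, j], out.unmeth[grn, j]])
        r_pool = np.concatenate([out.meth[red, j], out.unmeth[red, j]])
        if color_reference == "midpoint":
            # average of the two channels' order statistics on a common grid
            grid = np.linspace(0, 1, max(len(g_pool), len(r_pool)))
            gq = np.quantile(np.sort(g_pool), grid)
            rq = np.quantile(np.sort(r_pool), grid)
            ref = 0.5 * (gq + rq)
            for mask, pool in ((grn, g_pool), (red, r_pool)):
                out.meth[mask, j] = _quantile_map(out.meth[mask, j], pool, ref)
                out.unmeth[mask, j] = _quantile_map(out.unmeth[mask, j], pool, ref)
        else:
            ref_pool = g_pool if color_reference == "Grn" else r_pool
            moving = red if color_reference == "Grn" else grn
            pool = r_pool if color_reference == "Grn" else g_pool
            out.meth[moving, j] = _quantile_map(out.meth[moving, j], pool, ref_pool)
            out.unmeth[moving, j] = _quantile_map(out.unmeth[moving, j], pool, ref_pool)
    return out


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns to the mean of order statistics.

    Every column is replaced by the cross-column mean of sorted values at its
    own ranks; afterwards all columns share the identical sorted vector.
    Ties within a column receive the average of the target values over the
    tied ranks, so within-column rank order (with ties) is preserved.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if np.isnan(x).any():
        raise ValueError("missing values are not allowed")
    n, k = x.shape
    if k < 2:
        warnings.warn("single sample: quantile normalization is the identity", stacklevel=2)
        return x.copy()
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(k):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)
        mapped = target[ranks]
        # average the target over tied input values
        uniq, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        if len(uniq) < n:
            sums = np.bincount(inv, weights=mapped)
            mapped = (sums / counts)[inv]
        out[:, j] = mapped
    return out


def preprocess_pipeline(dataset: MethylationDataset, config: PreprocessConfig | None = None) -> MValueMatrix:
    """Run background subtraction, color adjustment, quantile normalization
    and M computation in that order.

    Quantile normalization acts on the stacked (meth over unmeth) matrix so
    both signal channels share one target distribution.
    """
    if config is None:
        config = PreprocessConfig()
    if dataset.n_probes == 0:
        raise DataValidationError("empty probe set")

    ds = dataset
    if config.do_background:
        log.info("background subtraction at quantile %.3g", config.background_quantile)
        ds = subtract_background(ds, config.background_quantile)
    if config.do_color:
        log.info("color-bias adjustment onto %s", config.color_reference)
        ds = adjust_color_bias(ds, config.color_reference)
    meth, unmeth = ds.meth, ds.unmeth
    if config.do_quantile and ds.n_samples >= 2:
        log.info("quantile normalization of stacked intensity matrix")
        stacked = quantile_normalize(np.vstack([meth, unmeth]))
        meth, unmeth = stacked[: ds.n_probes], stacked[ds.n_probes :]
    m = compute_m(meth, unmeth, config.m_offset)
    return MValueMatrix(ds.probe_ids, tuple(ds.samples.sample_ids), m, config.m_offset)
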