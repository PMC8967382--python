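"""Contrast- and luminance-encoding statistics.

The contrast-response curve is the two-parameter sigmoid

    f(x) = a * (1 / (1 + exp(k * x)) - 0.5)

with scaling parameter ``a`` and slope parameter ``k``; note ``f(0) = 0``
identically, and with this sign convention responses that *increase* with
contrast are fitted by ``k < 0`` (steepness comparisons use ``|k|``).
Parameter uncertainty comes from bootstrapping over recording units (flies
or ROIs) with replacement.

Luminance encoding is quantified by (i) the plug-in mutual information
between discrete luminance levels and a binned scalar response, and
(ii) a non-linearity index, the difference between Pearson and Spearman
correlation of response vs. luminance — exactly zero for any strictly
linear relationship and bounded in [-2, 2].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import pearsonr, spearmanr

__all__ = [
    "SigmoidFit",
    "contrast_sigmoid",
    "fit_contrast_sigmoid",
    "bootstrap_sigmoid",
    "mutual_information",
    "nonlinearity_index",
    "fit_log_slope",
]


def contrast_sigmoid(x, a: float, k: float):
    """Evaluate ``f(x) = a * (1/(1+exp(k*x)) - 0.5)``."""
    x = np.asarray(x, dtype=float)
    return a * (1.0 / (1.0 + np.exp(k * x)) - 0.5)


@dataclass
class SigmoidFit:
    """Point estimate and bootstrap distribution of the sigmoid parameters."""

    a: float
    k: float
    loss: float
    boot_a: np.ndarray = field(default_factory=lambda: np.empty(0))
    boot_k: np.ndarray = field(default_factory=lambda: np.empty(0))
    flagged: bool = False

    def __post_init__(self) -> None:
        if len(self.boot_a) != len(self.boot_k):
            raise ValueError("bootstrap samples for a and k must align")

    @property
    def n_boot(self) -> int:
        return len(self.boot_a)


def fit_contrast_sigmoid(
    contrasts: Sequence[float], responses: Sequence[float]
) -> SigmoidFit:
    """Least-squares fit of the contrast sigmoid.

    Multi-start nonlinear least squares over k in {±1, ±5, ±20}, with a
    initialized at the response range.  The (a, k) -> (-a, -k) symmetry of
    the model is resolved by reporting ``a >= 0``.  All-zero responses give
    a = 0 with unidentifiable k (flagged); non-convergence is also flagged
    rather than raised.
    """
    x = np.asarray(contrasts, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ValueError("contrasts and responses must align")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct contrast values")
    if np.allclose(y, 0.0):
        return SigmoidFit(a=0.0, k=0.0, loss=0.0, flagged=True)

    a0 = float(np.ptp(y)) or 1.0
    best = None
    ok = False
    for k0 in (1.0, -1.0, 5.0, -5.0, 20.0, -20.0):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = least_squares(
                lambda p: contrast_sigmoid(x, *p) - y,
                x0=[a0, k0],
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=2000,
            )
        loss = float(2.0 * res.cost)  # residual sum of squares
        if best is None or loss < best[0]:
            best = (loss, res.x)
            ok = res.success
    loss, (a, k) = best
    if a < 0:  # canonicalize the sign degeneracy
        a, k = -a, -k
    return SigmoidFit(a=float(a), k=float(k), loss=loss, flagged=not ok)


def bootstrap_sigmoid(
    contrasts: Sequence[float],
    responses: Sequence[float],
    units: Sequence,
    n_boot: int = 50,
    seed: int = 0,
) -> SigmoidFit:
    """Bootstrap the sigmoid fit over recording units.

    ``units`` labels each (contrast, response) sample with its resampling
    unit (fly or ROI).  Units are drawn with replacement ``n_boot`` times;
    each resample pools the samples of the drawn units and is refit.  The
    point estimate is the fit to the full data.
    """
    x = np.asarray(contrasts, dtype=float)
    y = np.asarray(responses, dtype=float)
    units = np.asarray(units)
    if not (len(x) == len(y) == len(units)):
        raise ValueError("contrasts, responses and units must align")
    uniq = np.unique(units)
    if len(uniq) < 2:
        warnings.warn("bootstrap over a single unit is degenerate", stacklevel=2)
    rng = np.random.default_rng(seed)

    point = fit_contrast_sigmoid(x, y)
    boot_a = np.empty(n_boot)
    boot_k = np.empty(n_boot)
    groups = {u: (x[units == u], y[units == u]) for u in uniq}
    for b in range(n_boot):
        draw = rng.choice(uniq, size=len(uniq), replace=True)
        xb = np.concatenate([groups[u][0] for u in draw])
        yb = np.concatenate([groups[u][1] for u in draw])
        fit = fit_contrast_sigmoid(xb, yb)
        boot_a[b], boot_k[b] = fit.a, fit.k
    return SigmoidFit(
        a=point.a, k=point.k, loss=point.loss,
        boot_a=boot_a, boot_k=boot_k, flagged=point.flagged,
    )


# ---------------------------------------------------------------------------
# information & linearity
# ---------------------------------------------------------------------------


def mutual_information(
    levels: Sequence,
    responses: Sequence[float],
    n_bins: int | None = None,
    shuffle_correction: bool = False,
    n_shuffle: int = 100,
    seed: int = 0,
) -> float:
    """Plug-in mutual information (bits) between discrete stimulus levels
    and a scalar response.

    Responses are discretized into ``n_bins`` equal-occupancy bins
    (default: one bin per stimulus level).  With ``shuffle_correction`` the
    mean MI of ``n_shuffle`` label permutations is subtracted, removing
    most of the positive plug-in bias (the corrected value may dip slightly
    below zero on independent data).
    """
    levels = np.asarray(levels)
    y = np.asarray(responses, dtype=float)
    if levels.shape != y.shape:
        raise ValueError("levels and responses must align")
    uniq = np.unique(levels)
    if len(uniq) < 2:
        warnings.warn("single stimulus level: MI is 0", stacklevel=2)
        return 0.0
    if n_bins is None:
        n_bins = len(uniq)

    edges = np.quantile(y, np.linspace(0.0, 1.0, n_bins + 1)[1:-1])
    bins = np.searchsorted(edges, y, side="right")

    def plug_in(lv, bv) -> float:
        joint = np.zeros((len(uniq), n_bins))
        for i, u in enumerate(uniq):
            sel = bv[lv == u]
            for b in sel:
                joint[i, b] += 1
        p = joint / joint.sum()
        px = p.sum(axis=1, keepdims=True)
        py = p.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = p * np.log2(p / (px * py))
        return float(np.nansum(terms))

    mi = plug_in(levels, bins)
    if shuffle_correction:
        rng = np.random.default_rng(seed)
        null = np.mean(
            [plug_in(rng.permutation(levels), bins) for _ in range(n_shuffle)]
        )
        mi -= null
    return mi


def nonlinearity_index(luminance: Sequence[float], responses: Sequence[float]) -> float:
    """Pearson correlation minus Spearman rank correlation.

    Zero for any strictly linear luminance-response relationship; positive
    or negative for convex/concave monotone relationships depending on the
    sign of the correlation.  Bounded in [-2, 2].
    """
    x = np.asarray(luminance, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need at least 3 aligned points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r = pearsonr(x, y).statistic
    rho = spearmanr(x, y).statistic
    return float(r - rho)


def fit_log_slope(
    luminance: Sequence[float],
    responses: Sequence[float],
    normalize: bool = False,
) -> tuple[float, float]:
    """Least-squares line ``y = a * log(luminance) + b`` (natural log).

    With ``normalize`` the responses are min-max scaled to [0, 1] before
    fitting (used when comparing slopes across modalities).  Returns
    ``(a, b)``.
    """
    x = np.asarray(luminance, dtype=float)
    y = np.asarray(responses, dtype=float)
    if (x <= 0).any():
        raise ValueError("luminances must be positive for a log fit")
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct luminances")
    if normalize:
        if np.ptp(y) == 0:
            raise ValueError("cannot normalize constant responses")
        y = (y - y.min()) / np.ptp(y)
    coeffs = np.polyfit(np.log(x), y, deg=1)
    return float(coeffs[0]), float(coeffs[1])
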