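"""Distance-decay ("RD-scaling") estimation.

RNA-DNA contact density decays with genomic distance from the RNA source
gene, analogous to the Hi-C distance decay. Per RNA, the decay is captured
as a multiplicative factor over the heterogeneity background,

    f(d_j) = (O_j / N) / p_bg_j

for every cis bin j at distance d_j, smoothed with a cubic smoothing spline
in double-logarithmic coordinates. Estimation is two-step: candidate peak
bins (significantly high coverage under the step-1 curve) are removed and
the spline refitted once, so real binding sites do not inflate the presumed
background decay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline, make_interp_spline, make_smoothing_spline

from . import peak_calling

logger = logging.getLogger(__name__)

#: fewest distinct (log-distance, log-factor) points a spline fit needs;
#: below this the model degrades to the flat f ≡ 1
MIN_SPLINE_POINTS = 4


@dataclass
class ScalingModel:
    """Smoothed scaling factor f(d), evaluable at any distance d >= 1.

    Outside the fitted log10-distance domain the boundary value is returned
    (flat extrapolation); a model without a spline is the constant fallback.
    """

    spline: BSpline | None = None
    log_domain: tuple[float, float] = (0.0, 0.0)
    constant: float = 1.0
    rna_name: str = ""
    n_points: int = 0
    n_excluded: int = 0
    step: int = 0

    def __call__(self, d) -> np.ndarray:
        d = np.maximum(np.asarray(d, float), 1.0)
        if self.spline is None:
            return np.full(d.shape, self.constant)
        x = np.clip(np.log10(d), *self.log_domain)
        return np.power(10.0, np.asarray(self.spline(x), float))

    @property
    def is_constant(self) -> bool:
        return self.spline is None


def raw_scaling_points(
    counts: np.ndarray, n_total: int, bg_prob: np.ndarray, distance: np.ndarray
):
    """Per-cis-bin raw factors f̂ = (O/N)/p_bg; zero-count bins flagged.

    Zero bins yield f̂ = 0 whose log is undefined — they are kept (a dropped
    empty bin would bias the distal curve upward) and handled by the
    half-count offset in :func:`fit_spline`.
    """
    counts = np.asarray(counts, float)
    bg_prob = np.asarray(bg_prob, float)
    if n_total <= 0:
        raise ValueError("N must be positive to estimate scaling")
    if np.any(bg_prob <= 0):
        raise ValueError("background probabilities must be positive on cis bins")
    fhat = (counts / n_total) / bg_prob
    return np.asarray(distance, float), fhat, counts == 0


#: width (dex) of the log-distance windows the raw profile is averaged in
#: before smoothing; averaging on the factor scale keeps the estimate
#: unbiased where per-bin counts are low (the log of a noisy small count is
#: biased downward), as in distance-decay curve estimation for Hi-C
LOG_AGG_DEX = 0.05


def fit_spline(
    distance: np.ndarray,
    fhat: np.ndarray,
    epsilon: float,
    smooth: float | None = None,
    rna_name: str = "",
    step: int = 1,
) -> ScalingModel:
    """Cubic smoothing spline through the log-aggregated decay profile.

    Raw factors are averaged (on the factor scale) within log10-distance
    windows of ``LOG_AGG_DEX`` dex, then the spline is fitted to
    (mean log10 d, log10(mean f̂ + ε)) with the fitter's generalized
    cross-validation smoothing by default. ``epsilon`` is the half-count
    offset 0.5 / (N * max_j p_bg_j) that keeps empty windows on the log
    scale. Fewer than 4 usable windows falls back to f ≡ 1.
    """
    distance = np.asarray(distance, float)
    fhat = np.asarray(fhat, float)
    ok = np.isfinite(distance) & np.isfinite(fhat) & (distance >= 1)
    x = np.log10(distance[ok])
    f = fhat[ok]
    order = np.argsort(x)
    x, f = x[order], f[order]
    win = np.floor(x / LOG_AGG_DEX).astype(np.int64)
    uwin, inverse = np.unique(win, return_inverse=True)
    n_in = np.bincount(inverse)
    ux = np.bincount(inverse, weights=x) / n_in
    uf = np.bincount(inverse, weights=f) / n_in
    uy = np.log10(uf + epsilon)
    if len(ux) < MIN_SPLINE_POINTS:
        logger.warning(
            "%s: %d usable scaling points (<%d); using flat f=1",
            rna_name, len(ux), MIN_SPLINE_POINTS,
        )
        return ScalingModel(rna_name=rna_name, n_points=len(ux), step=step)
    if len(ux) == MIN_SPLINE_POINTS:
        spline = make_interp_spline(ux, uy, k=3)
    else:
        spline = make_smoothing_spline(ux, uy, lam=smooth)
    return ScalingModel(
        spline=spline,
        log_domain=(float(ux[0]), float(ux[-1])),
        rna_name=rna_name,
        n_points=len(ux),
        step=step,
    )


def epsilon_offset(n_total: int, bg_prob: np.ndarray) -> float:
    """Half-count offset on the factor scale: 0.5 / (N * max_j p_bg_j)."""
    return 0.5 / (n_total * float(np.max(bg_prob)))


def refine_two_step(
    model_step1: ScalingModel,
    counts: np.ndarray,
    n_total: int,
    bg_prob: np.ndarray,
    distance: np.ndarray,
    cis_mass: float,
    alpha_refine: float = 0.05,
    smooth: float | None = None,
) -> ScalingModel:
    """Refit after removing bins with statistically high coverage.

    Step-1 probabilities f1(d) * p_bg are renormalized to the cis contact
    mass (as in peak calling), right-sided binomial p-values computed for
    non-empty bins, BH-adjusted within the RNA, and bins with q <
    ``alpha_refine`` dropped before the single refit. Exactly two steps; if
    nothing is removed (or everything would be) the step-1 model stands.
    """
    counts = np.asarray(counts, float)
    raw = model_step1(distance) * np.asarray(bg_prob, float)
    total = raw.sum()
    if total <= 0 or n_total <= 0:
        return model_step1
    probs = raw / total * cis_mass
    nonzero = counts > 0
    remove = np.zeros(len(counts), bool)
    if alpha_refine > 0 and nonzero.any():
        pvals = peak_calling.binom_right_pvalue(
            counts[nonzero].astype(np.int64), n_total, probs[nonzero]
        )
        qvals = peak_calling.bh_adjust(pvals)
        remove[np.nonzero(nonzero)[0][qvals < alpha_refine]] = True
    if not remove.any():
        return model_step1
    keep = ~remove
    if keep.sum() == 0:
        logger.warning("%s: refinement removed all bins; keeping step-1 model",
                       model_step1.rna_name)
        return model_step1
    eps = epsilon_offset(n_total, bg_prob)
    d_keep, fhat_keep, _ = raw_scaling_points(
        counts[keep], n_total, np.asarray(bg_prob, float)[keep],
        np.asarray(distance, float)[keep],
    )
    model2 = fit_spline(
        d_keep, fhat_keep, eps, smooth=smooth, rna_name=model_step1.rna_name, step=2
    )
    model2.n_excluded = int(remove.sum())
    return model2


def estimate_scaling(
    counts: np.ndarray,
    n_total: int,
    bg_prob: np.ndarray,
    distance: np.ndarray,
    cis_mass: float,
    alpha_refine: float = 0.05,
    smooth: float | None = None,
    rna_name: str = "",
) -> tuple[ScalingModel, ScalingModel]:
    """Full two-step estimate on one RNA's non-gene-body cis bins.

    Returns (step-1 model, step-2 model); the step-2 model is the one used
    downstream. All-empty cis data degrades to the flat model.
    """
    counts = np.asarray(counts)
    if counts.sum() == 0:
        logger.warning("%s: no cis contacts; using flat f=1", rna_name)
        flat = ScalingModel(rna_name=rna_name)
        return flat, flat
    d, fhat, _ = raw_scaling_points(counts, n_total, bg_prob, distance)
    eps = epsilon_offset(n_total, bg_prob)
    model1 = fit_spline(d, fhat, eps, smooth=smooth, rna_name=rna_name, step=1)
    model2 = refine_two_step(
        model1, counts, n_total, bg_prob, distance, cis_mass,
        alpha_refine=alpha_refine, smooth=smooth,
    )
    return model1, model2
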