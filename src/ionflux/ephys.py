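"""Single-channel recording analysis.

All-points histograms of a current trace show the closed and open levels as
two Gaussian peaks; the distance between the fitted means is the
single-channel current i at that holding potential.  Per-polarity OLS of i
against voltage gives the outward/inward conductances γ_o and γ_i, compared
within a construct by a paired t-test and across constructs by one-way
ANOVA with Dunnett's test against the control at family-wise α.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, signal, stats

from .permeation import rectification_ratio


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """A sampled patch-clamp current trace at one holding potential."""

    current: np.ndarray  # pA
    rate_hz: float = 20000.0
    holding_mV: float = 0.0
    patch_id: str = ""
    construct: str = ""

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, float)
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.current)):
            raise ValueError("trace contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.current) / self.rate_hz


@dataclass
class TwoGaussianFit:
    """Sum-of-two-Gaussians fit to an all-points histogram."""

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    w1: float
    w2: float
    residual: float

    @property
    def i_single(self) -> float:
        """Single-channel current |μ₂ − μ₁| (pA)."""
        return abs(self.mu2 - self.mu1)


@dataclass
class PatchSummary:
    """Per-patch slope conductances."""

    construct: str
    patch_id: str
    gamma_o: float  # pS
    gamma_i: float  # pS
    n_pos: int
    n_neg: int
    ratio: float = field(init=False)

    def __post_init__(self) -> None:
        self.ratio = rectification_ratio(self.gamma_o, self.gamma_i)


# ---------------------------------------------------------------------------
# histogram and mixture fit
# ---------------------------------------------------------------------------

def all_points_histogram(rec: Recording, bin_width: float = 0.1
                         ) -> Tuple[np.ndarray, np.ndarray]:
    """Histogram of every sample; counts sum to the number of samples.

    Bin edges are aligned to multiples of ``bin_width``.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    lo = np.floor(rec.current.min() / bin_width) * bin_width
    hi = np.ceil(rec.current.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width * 1.5, bin_width)
    counts, edges = np.histogram(rec.current, bins=edges)
    return counts, edges


def _double_gauss(x, a1, mu1, s1, a2, mu2, s2):
    return (a1 * np.exp(-0.5 * ((x - mu1) / s1) ** 2)
            + a2 * np.exp(-0.5 * ((x - mu2) / s2) ** 2))


def fit_two_gaussians(counts: np.ndarray, edges: np.ndarray,
                      min_separation: float = 1.0) -> TwoGaussianFit:
    """Nonlinear least squares of two Gaussians on an all-points histogram.

    Initialization uses the two tallest peaks at least ``min_separation``
    (pA) apart; among candidate peak pairs the one with the largest combined
    weight wins (the dominant conductance level when more than two levels
    are present).  Raises if no bimodality is detectable — usually a sign
    the trace is too short or the channel never opened.
    """
    centers = (edges[:-1] + edges[1:]) / 2
    bin_w = edges[1] - edges[0]
    dist = max(1, int(round(min_separation / bin_w)))
    smooth = np.convolve(counts.astype(float), np.ones(3) / 3, mode="same")
    # zero-pad so levels sitting in the first/last bin are still peaks
    padded = np.concatenate([[0.0], smooth, [0.0]])
    peaks, props = signal.find_peaks(padded, distance=dist,
                                     prominence=max(1.0, 0.01 * counts.max()))
    peaks = peaks - 1
    if len(peaks) < 2:
        raise ValueError("histogram is unimodal; record a longer trace or "
                         "check that the channel opens")
    order = peaks[np.argsort(smooth[peaks])[::-1]]
    p1 = order[0]
    p2 = next((p for p in order[1:]
               if abs(centers[p] - centers[p1]) >= min_separation), None)
    if p2 is None:
        raise ValueError("no second peak separated from the dominant one")
    guess = [smooth[p1], centers[p1], max(bin_w, 0.5),
             smooth[p2], centers[p2], max(bin_w, 0.5)]
    lo = [0, centers[0] - 1, 1e-3, 0, centers[0] - 1, 1e-3]
    hi = [counts.max() * 2.0, centers[-1] + 1, np.ptp(centers),
          counts.max() * 2.0, centers[-1] + 1, np.ptp(centers)]
    try:
        popt, _ = optimize.curve_fit(_double_gauss, centers, counts, p0=guess,
                                     bounds=(lo, hi), maxfev=20000)
        a1, mu1, s1, a2, mu2, s2 = popt
    except RuntimeError:
        # near-zero-noise traces collapse each level into one or two bins;
        # the least-squares problem is ill-posed there, but per-peak moments
        # are exact
        split = 0.5 * (centers[p1] + centers[p2])
        side1 = (centers <= split) if centers[p1] <= split else (centers > split)
        popt = []
        for mask in (side1, ~side1):
            w = counts[mask].astype(float)
            mu = np.average(centers[mask], weights=w)
            sd = np.sqrt(max(np.average((centers[mask] - mu) ** 2, weights=w),
                             (bin_w / 4) ** 2))
            popt += [w.max(), mu, sd]
        a1, mu1, s1, a2, mu2, s2 = popt
    area1 = a1 * s1
    area2 = a2 * s2
    total = area1 + area2
    resid = float(np.sqrt(np.mean(
        (_double_gauss(centers, *popt) - counts) ** 2)))
    return TwoGaussianFit(mu1=float(mu1), mu2=float(mu2), sigma1=float(s1),
                          sigma2=float(s2), w1=float(area1 / total),
                          w2=float(area2 / total), residual=resid)


def single_channel_current(rec: Recording, bin_width: float = 0.1,
                           min_separation: float = 1.0) -> float:
    """Signed single-channel current of a trace (pA).

    Magnitude from the two-Gaussian fit; sign from the holding potential
    (the open level moves with γ·V).
    """
    counts, edges = all_points_histogram(rec, bin_width)
    fit = fit_two_gaussians(counts, edges, min_separation)
    sign = 1.0 if rec.holding_mV >= 0 else -1.0
    return sign * fit.i_single


# ---------------------------------------------------------------------------
# conductances and statistics
# ---------------------------------------------------------------------------

def patch_conductances(currents_pA: Sequence[float],
                       potentials_mV: Sequence[float],
                       construct: str = "", patch_id: str = ""
                       ) -> PatchSummary:
    """Per-polarity OLS slopes of single-channel current vs voltage (pS)."""
    i = np.asarray(currents_pA, float)
    v = np.asarray(potentials_mV, float)
    pos = v >= 0
    neg = v <= 0
    if len(np.unique(v[pos])) < 2 or len(np.unique(v[neg])) < 2:
        raise ValueError("need >= 2 potentials on each polarity")
    go = stats.linregress(v[pos], i[pos]).slope * 1000.0
    gi = stats.linregress(v[neg], i[neg]).slope * 1000.0
    return PatchSummary(construct=construct, patch_id=patch_id,
                        gamma_o=go, gamma_i=gi,
                        n_pos=int(pos.sum()), n_neg=int(neg.sum()))


def paired_t(gamma_o: Sequence[float], gamma_i: Sequence[float]
             ) -> Tuple[float, float]:
    """Classical paired t-test (two-sided, n−1 df) between γ_o and γ_i.

    Degenerate inputs: identical lists give (0, 1); equal nonzero
    differences with zero spread give (±inf, 0).
    """
    a = np.asarray(gamma_o, float)
    b = np.asarray(gamma_i, float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need equal-length lists with n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def _pooled_sd(groups: Sequence[np.ndarray]) -> Tuple[float, int]:
    df = sum(len(g) - 1 for g in groups)
    ss = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return np.sqrt(ss / df), df


def dunnett_critical_value(n_per_group: Sequence[int], df: int,
                           alpha: float = 0.05, n_mc: int = 100000,
                           seed: int = 12345) -> float:
    """Two-sided Dunnett critical value by Monte Carlo.

    Draws the joint null distribution of the k−1 comparison t statistics
    (common control, shared pooled variance) and returns the 1−α quantile
    of max |t_j|; with k = 2 this reduces to the ordinary two-sample t
    critical value up to Monte Carlo error.
    """
    n0 = n_per_group[0]
    others = n_per_group[1:]
    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal(n_mc) / np.sqrt(n0)
    s = np.sqrt(rng.chisquare(df, size=n_mc) / df)
    t_max = np.zeros(n_mc)
    for nj in others:
        zj = rng.standard_normal(n_mc) / np.sqrt(nj)
        tj = np.abs(zj - z0) / (s * np.sqrt(1.0 / nj + 1.0 / n0))
        np.maximum(t_max, tj, out=t_max)
    return float(np.quantile(t_max, 1.0 - alpha))


def anova_dunnett(groups: Dict[str, Sequence[float]], control: str,
                  alpha: float = 0.05, n_mc: int = 100000,
                  seed: int = 12345) -> dict:
    """One-way ANOVA plus Dunnett's many-to-one comparisons vs a control.

    Returns a dict with the F statistic, its p-value, the Monte Carlo
    Dunnett critical value, and per-group comparison t statistics with
    reject/accept decisions at family-wise ``alpha``.
    """
    if control not in groups:
        raise KeyError(f"control group {control!r} missing")
    names = [control] + [k for k in groups if k != control]
    arrs = [np.asarray(groups[k], float) for k in names]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    for k, g in zip(names, arrs):
        if len(g) < 2:
            raise ValueError(f"group {k!r} has n < 2")
    all_vals = np.concatenate(arrs)
    grand = all_vals.mean()
    ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in arrs)
    ss_w = sum(((g - g.mean()) ** 2).sum() for g in arrs)
    df_b = len(arrs) - 1
    df_w = len(all_vals) - len(arrs)
    if ss_w == 0:
        raise ZeroDivisionError("zero within-group variance; F undefined")
    f_stat = (ss_b / df_b) / (ss_w / df_w)
    p_f = float(stats.f.sf(f_stat, df_b, df_w))
    sp, df = _pooled_sd(arrs)
    crit = dunnett_critical_value([len(g) for g in arrs], df, alpha,
                                  n_mc=n_mc, seed=seed)
    comparisons = {}
    g0 = arrs[0]
    for k, g in zip(names[1:], arrs[1:]):
        t = (g.mean() - g0.mean()) / (sp * np.sqrt(1 / len(g) + 1 / len(g0)))
        comparisons[k] = {"t": float(t), "significant": bool(abs(t) > crit)}
    return {"F": float(f_stat), "p": p_f, "df": (df_b, df_w),
            "dunnett_critical": crit, "alpha": alpha,
            "comparisons": comparisons}
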