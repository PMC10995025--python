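"""Technical image-quality analysis (line-pair MTF) and agreement statistics.

MTF from bar patterns
---------------------
For each bar group the modulation is measured as the noise-corrected
standard deviation inside a rectangular ROI,

    M_i = sqrt(max(sd(ROI_i)^2 - sd(noise ROI)^2, 0)),

the practical standard-deviation method for line-pair phantoms.  Two
normalization conventions are provided:

* ``material_pair`` — divide by ``M0 = |mean(A) - mean(B)| / 2``, half the
  contrast between two uniform reference materials.  An ideal, blur-free
  bar pattern spanning the material levels then reads exactly 1, i.e. the
  curve is the bar-pattern (square-wave) contrast transfer normalized to
  unity at zero frequency.  The classical pi*sqrt(2)/4 square-to-sine
  factor is a global scalar under this convention and is deliberately not
  applied; the normalization is fixed by the unit test on the noise-free
  phantom.
* ``max_intensity`` — rescale the curve so its maximum sample equals 1,
  for images whose grayscales have been distorted (e.g. by learned
  restoration) so that material levels are no longer trustworthy.

Curves are measured per slice; the reported value is the across-slice mean
with a t-based 95% confidence half-width.  MTF50/MTF10 readouts come from
linear interpolation between bracketing samples or from the root of a
fitted third-order polynomial trendline.

Agreement statistics
--------------------
Pearson correlation with Fisher-z confidence intervals, Bland–Altman bias
and limits of agreement, linearly weighted Cohen's kappa with its
asymptotic confidence interval, and the Wilcoxon signed-rank test with
Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .volio import Volume

__all__ = [
    "MTFCurve",
    "RoiSet",
    "mtf_from_line_pairs",
    "mtf_percentiles",
    "pearson_r",
    "bland_altman",
    "weighted_kappa",
    "wilcoxon_signed_rank",
]

Rect = tuple[int, int, int, int]  # (y0, y1, x0, x1), half-open


@dataclass
class RoiSet:
    """Rectangular ROIs in (row, column) coordinates, shared by all slices."""

    groups: list[Rect]
    noise: Rect
    materials: dict[str, Rect] = field(default_factory=dict)

    def validate(self, shape: tuple[int, int]) -> None:
        def check(r: Rect, name: str) -> None:
            y0, y1, x0, x1 = r
            if not (0 <= y0 < y1 <= shape[0] and 0 <= x0 < x1 <= shape[1]):
                raise ValueError(f"ROI {name} {r} outside image bounds {shape}")
        for i, r in enumerate(self.groups):
            check(r, f"group[{i}]")
        check(self.noise, "noise")
        for k, r in self.materials.items():
            check(r, f"material[{k}]")


@dataclass
class MTFCurve:
    frequencies_lp_cm: np.ndarray
    mtf: np.ndarray
    ci_halfwidth: np.ndarray
    normalization: str
    mtf50_lp_cm: float | None = None
    mtf10_lp_cm: float | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frequencies_lp_cm) <= 0):
            raise ValueError("frequencies must be strictly increasing")


def _roi(img: np.ndarray, rect: Rect) -> np.ndarray:
    y0, y1, x0, x1 = rect
    return img[y0:y1, x0:x1]


def mtf_from_line_pairs(
    vol: Volume,
    rois: RoiSet,
    freqs: np.ndarray | list[float],
    normalization: str = "material_pair",
) -> MTFCurve:
    """Measure the MTF of a bar-pattern phantom volume (one value per group,
    mean and t-based 95% CI across slices)."""
    freqs = np.asarray(freqs, dtype=float)
    if len(freqs) != len(rois.groups):
        raise ValueError(
            f"{len(freqs)} frequencies given for {len(rois.groups)} group ROIs")
    if normalization not in ("material_pair", "max_intensity"):
        raise ValueError(f"unknown normalization {normalization!r}")
    data = vol.data.astype(np.float64)
    rois.validate(data.shape[1:])

    per_slice = np.zeros((data.shape[0], len(freqs)))
    for z in range(data.shape[0]):
        img = data[z]
        noise_sd = _roi(img, rois.noise).std(ddof=1)
        mods = np.array([
            np.sqrt(max(_roi(img, r).std(ddof=1) ** 2 - noise_sd ** 2, 0.0))
            for r in rois.groups
        ])
        if normalization == "material_pair":
            if len(rois.materials) < 2:
                raise ValueError("material_pair normalization needs two material ROIs")
            (a, b) = list(rois.materials.values())[:2]
            m0 = abs(_roi(img, a).mean() - _roi(img, b).mean()) / 2.0
            if m0 <= 0:
                raise ValueError("zero material contrast; cannot normalize")
            per_slice[z] = mods / m0
        else:
            per_slice[z] = mods

    mean = per_slice.mean(axis=0)
    n = data.shape[0]
    if n > 1:
        sem = per_slice.std(axis=0, ddof=1) / np.sqrt(n)
        ci = sem * stats.t.ppf(0.975, n - 1)
    else:
        ci = np.zeros_like(mean)
    if normalization == "max_intensity":
        peak = mean.max()
        if peak <= 0:
            raise ValueError("flat curve; cannot normalize by maximum")
        mean = mean / peak
        ci = ci / peak

    curve = MTFCurve(frequencies_lp_cm=freqs, mtf=mean, ci_halfwidth=ci,
                     normalization=normalization)
    curve.mtf50_lp_cm = mtf_percentiles(curve, [0.5])[0]
    curve.mtf10_lp_cm = mtf_percentiles(curve, [0.1])[0]
    return curve


def _poly_crossing(freqs: np.ndarray, mtf: np.ndarray, level: float) -> float | None:
    coeffs = np.polyfit(freqs, mtf, 3)
    roots = np.roots(coeffs - np.array([0, 0, 0, level]))
    real = sorted(
        float(r.real) for r in roots
        if abs(r.imag) < 1e-9 and freqs[0] <= r.real <= freqs[-1]
    )
    return real[0] if real else None


def mtf_percentiles(curve: MTFCurve, levels: list[float] | None = None,
                    method: str = "linear") -> list[float | None]:
    """Frequencies at which the curve first falls to each level, scanning
    from the low-frequency side; ``None`` when the level is never crossed.

    ``linear`` interpolates between the bracketing samples (exact on samples
    that hit the level); ``poly3`` uses the root of a third-order polynomial
    trendline fitted to the samples.
    """
    levels = [0.5, 0.1] if levels is None else levels
    f, m = curve.frequencies_lp_cm, curve.mtf
    if len(f) < 2:
        raise ValueError("need at least two samples")
    out: list[float | None] = []
    for level in levels:
        if method == "poly3":
            out.append(_poly_crossing(f, m, level))
            continue
        if method != "linear":
            raise ValueError(f"unknown method {method!r}")
        hit = None
        for i in range(len(f)):
            if m[i] == level:
                hit = float(f[i])
                break
            if i and (m[i - 1] - level) * (m[i] - level) < 0:
                frac = (m[i - 1] - level) / (m[i - 1] - m[i])
                hit = float(f[i - 1] + frac * (f[i] - f[i - 1]))
                break
        out.append(hit)
    return out


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------

def pearson_r(x, y) -> tuple[float, tuple[float, float]]:
    """Product-moment correlation with a Fisher-z 95% CI
    (z +- 1.96/sqrt(n-3))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson_r needs paired samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the inputs")
    r = float(stats.pearsonr(x, y).statistic)
    n = len(x)
    if n < 4 or abs(r) >= 1.0:
        return r, (float("nan"), float("nan"))
    z = np.arctanh(r)
    half = 1.96 / np.sqrt(n - 3)
    return r, (float(np.tanh(z - half)), float(np.tanh(z + half)))


def bland_altman(a, b) -> tuple[float, float, float, float]:
    """Bias, sd of the paired differences (ddof=1) and the 95% limits of
    agreement ``bias +- 1.96 sd``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if len(a) < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, sd, bias - 1.96 * sd, bias + 1.96 * sd


def weighted_kappa(r1, r2, n_levels: int,
                   weights: str = "linear") -> tuple[float, tuple[float, float]]:
    """Cohen's kappa with linear disagreement weights and its asymptotic
    95% CI (Fleiss–Cohen–Everitt large-sample variance).

    ``kappa = 1 - sum(w o) / sum(w e)`` with disagreement weights
    ``w_ij = |i-j|/(n_levels-1)``, observed proportions ``o`` and chance
    proportions ``e`` (outer product of the marginals).
    """
    r1 = np.asarray(r1, dtype=int)
    r2 = np.asarray(r2, dtype=int)
    if r1.shape != r2.shape:
        raise ValueError("rating vectors differ in length")
    if np.any((r1 < 1) | (r1 > n_levels) | (r2 < 1) | (r2 > n_levels)):
        raise ValueError(f"ratings must lie in 1..{n_levels}")
    n = len(r1)
    obs = np.zeros((n_levels, n_levels))
    for i, j in zip(r1 - 1, r2 - 1):
        obs[i, j] += 1
    obs /= n
    p1, p2 = obs.sum(axis=1), obs.sum(axis=0)
    if np.count_nonzero(p1) < 2 or np.count_nonzero(p2) < 2:
        raise ValueError("degenerate marginals: a rater used a single category")
    exp = np.outer(p1, p2)
    if weights != "linear":
        raise ValueError("only linear weights are implemented")
    i = np.arange(n_levels)
    w_dis = np.abs(i[:, None] - i[None, :]) / (n_levels - 1)
    sum_wo = float((w_dis * obs).sum())
    sum_we = float((w_dis * exp).sum())
    kappa = 1.0 - sum_wo / sum_we
    # asymptotic variance with agreement weights v = 1 - w
    v = 1.0 - w_dis
    v_bar_i = (v * p2[None, :]).sum(axis=1)   # row expectation
    v_bar_j = (v * p1[:, None]).sum(axis=0)   # column expectation
    p_v = float((v * exp).sum())              # expected agreement = 1 - sum_we
    p_o = float((v * obs).sum())
    term = (obs * (v - (v_bar_i[:, None] + v_bar_j[None, :]) * (1 - kappa)) ** 2).sum()
    var = (term - (kappa - p_v * (1 - kappa)) ** 2) / (n * (1 - p_v) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    return float(kappa), (float(kappa - 1.96 * se), float(kappa + 1.96 * se))


def wilcoxon_signed_rank(a, b, bonferroni_m: int = 1) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples, zero
    differences dropped; exact null distribution for n <= 25 (no ties),
    normal approximation otherwise.  Returns ``(statistic,
    min(1, m * p))``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples differ in length")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all differences are zero; test undefined")
    has_ties = len(np.unique(np.abs(d))) < len(d)
    method = "approx" if (len(d) > 25 or has_ties) else "exact"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         method=method, correction=(method == "approx"))
    return float(res.statistic), float(min(1.0, bonferroni_m * res.pvalue))
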