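"""Full-reference quality metrics for enhancement and colorization.

Grayscale metrics
-----------------
* ``psnr`` — peak signal-to-noise ratio against a 255 peak, in dB.  Used to
  score luminance round-trip fidelity of a color map: the original grayscale
  image versus the luminance regenerated from its colorized output.
* ``svr_statistics`` — statistics of visual representation: the relative
  change in global standard deviation (contrast measurement) and in global
  mean (intensity measurement) from original to processed.  Positive contrast
  means a higher-contrast result; negative intensity means a darker one.
  The exact published formulas live in external references; this
  relative-change reconstruction is dimensionless and reproduces the
  expected sign behaviour, and is documented as a reconstruction.
* ``uiq`` — Wang–Bovik universal image quality index on 8x8 sliding windows
  (correlation x luminance x contrast distortion), in [-1, 1].

Color metrics
-------------
* ``cie94_delta_e`` — mean per-pixel CIE94 color difference in L*a*b*
  (graphic-arts constants kL=1, K1=0.045, K2=0.015).
* ``color_similarity`` — SSIM / MSSIM / SHSIM evaluated on the Cb and Cr
  chrominance planes of full-range BT.601 YCbCr.  SSIM is the single global
  window variant; MSSIM averages the local 11x11 Gaussian-window similarity
  map; SHSIM modulates the local similarity by a hue-agreement term
  ``1 - |dh|/pi`` on window-averaged chroma angles (a documented variant —
  the exact published form is in an external reference).
* ``colorfulness`` / ``cef`` — the opponent-channel colorfulness metric
  CM = sqrt(s_rg^2 + s_yb^2) + 0.3 * sqrt(m_rg^2 + m_yb^2) and the
  processed/original CM ratio (color enhancement factor, > 1 means more
  colorful).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from scipy.signal import convolve2d
from skimage import color as _skcolor

from .io import as_gray, as_rgb, rgb_to_ycbcr

__all__ = [
    "MetricsReport",
    "psnr",
    "svr_statistics",
    "uiq",
    "cie94_delta_e",
    "color_similarity",
    "colorfulness",
    "cef",
    "evaluate_pair",
]


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"image dimensions differ: {a.shape} vs {b.shape}")


def psnr(reference: np.ndarray, test: np.ndarray) -> float:
    """``10 log10(255^2 / MSE)`` in dB; identical images give ``inf``."""
    reference = as_gray(reference)
    test = as_gray(test)
    _check_same_shape(reference, test)
    mse = np.mean((reference.astype(np.float64) - test.astype(np.float64)) ** 2)
    if mse == 0:
        return math.inf
    return 10.0 * math.log10(255.0 ** 2 / mse)


def svr_statistics(original: np.ndarray, processed: np.ndarray) -> tuple[float, float]:
    """Relative contrast and intensity change ``(contrast, intensity)``.

    contrast  = (sigma(processed) - sigma(original)) / sigma(original)
    intensity = (mean(processed)  - mean(original))  / mean(original)

    A constant original (sigma = 0) or an all-zero original (mean = 0) makes
    the respective statistic undefined; NaN is returned as the sentinel.
    """
    original = as_gray(original).astype(np.float64)
    processed = as_gray(processed).astype(np.float64)
    _check_same_shape(original, processed)
    mu_o, mu_p = original.mean(), processed.mean()
    sd_o, sd_p = original.std(), processed.std()
    contrast = (sd_p - sd_o) / sd_o if sd_o > 0 else math.nan
    intensity = (mu_p - mu_o) / mu_o if mu_o > 0 else math.nan
    return contrast, intensity


def _sliding_mean(x: np.ndarray, win: int) -> np.ndarray:
    kernel = np.full((win, win), 1.0 / (win * win))
    return convolve2d(x, kernel, mode="valid")


def uiq(original: np.ndarray, processed: np.ndarray, window: int = 8) -> float:
    """Universal image quality index Q averaged over sliding windows.

    Per window, ``Q = 4 s_xy mx my / ((s_x^2 + s_y^2)(mx^2 + my^2))``; the
    original implementation's conventions are kept for degenerate windows
    (Q = 1 when both denominator factors vanish; the luminance term alone
    when only the variance factor vanishes).
    """
    x = as_gray(original).astype(np.float64)
    y = as_gray(processed).astype(np.float64)
    _check_same_shape(x, y)
    if min(x.shape) < window:
        raise ValueError(f"images must admit at least one {window}x{window} window")
    mx = _sliding_mean(x, window)
    my = _sliding_mean(y, window)
    vx = _sliding_mean(x * x, window) - mx * mx
    vy = _sliding_mean(y * y, window) - my * my
    cov = _sliding_mean(x * y, window) - mx * my
    d1 = vx + vy
    d2 = mx * mx + my * my
    q = np.ones_like(d1)
    both = (d1 != 0) & (d2 != 0)
    q[both] = 4.0 * cov[both] * mx[both] * my[both] / (d1[both] * d2[both])
    lum_only = (d1 == 0) & (d2 != 0)
    q[lum_only] = 2.0 * mx[lum_only] * my[lum_only] / d2[lum_only]
    return float(np.clip(q.mean(), -1.0, 1.0))


def cie94_delta_e(original: np.ndarray, processed: np.ndarray) -> float:
    """Mean per-pixel CIE94 color difference (graphic-arts constants).

    Evaluated directly from its definition so that identical pixels give an
    exact zero: with dC = C1 - C2 and dH^2 = da^2 + db^2 - dC^2 (floored at
    0 against cancellation noise),

        dE94 = sqrt((dL/kL)^2 + (dC/(1 + K1 C1))^2 + (dH/(1 + K2 C1))^2)
    """
    original = as_rgb(original)
    processed = as_rgb(processed)
    _check_same_shape(original, processed)
    lab1 = _skcolor.rgb2lab(original)
    lab2 = _skcolor.rgb2lab(processed)
    dl = lab1[..., 0] - lab2[..., 0]
    da = lab1[..., 1] - lab2[..., 1]
    db = lab1[..., 2] - lab2[..., 2]
    c1 = np.hypot(lab1[..., 1], lab1[..., 2])
    c2 = np.hypot(lab2[..., 1], lab2[..., 2])
    dc = c1 - c2
    dh2 = np.maximum(da * da + db * db - dc * dc, 0.0)
    k1, k2 = 0.045, 0.015
    de = np.sqrt(dl * dl + (dc / (1.0 + k1 * c1)) ** 2
                 + dh2 / (1.0 + k2 * c1) ** 2)
    return float(np.mean(de))


# -- SSIM family on chrominance planes --------------------------------------

_C1 = (0.01 * 255.0) ** 2
_C2 = (0.03 * 255.0) ** 2


def _gaussian_kernel(win: int = 11, sigma: float = 1.5) -> np.ndarray:
    r = win // 2
    g = np.exp(-0.5 * (np.arange(-r, r + 1) / sigma) ** 2)
    g /= g.sum()
    return np.outer(g, g)


def _ssim_map(x: np.ndarray, y: np.ndarray, win: int = 11,
              sigma: float = 1.5) -> np.ndarray:
    """Local structural-similarity map with Gaussian-weighted window
    statistics, valid-mode (no padded borders)."""
    k = _gaussian_kernel(win, sigma)
    mx = convolve2d(x, k, mode="valid")
    my = convolve2d(y, k, mode="valid")
    vx = convolve2d(x * x, k, mode="valid") - mx * mx
    vy = convolve2d(y * y, k, mode="valid") - my * my
    cov = convolve2d(x * y, k, mode="valid") - mx * my
    return ((2 * mx * my + _C1) * (2 * cov + _C2)) / \
           ((mx * mx + my * my + _C1) * (vx + vy + _C2))


def _ssim_global(x: np.ndarray, y: np.ndarray) -> float:
    """Single-window SSIM over whole-image statistics."""
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = np.mean((x - mx) * (y - my))
    return float(((2 * mx * my + _C1) * (2 * cov + _C2)) /
                 ((mx * mx + my * my + _C1) * (vx + vy + _C2)))


def _window_hue(cb: np.ndarray, cr: np.ndarray, win: int = 11,
                sigma: float = 1.5) -> np.ndarray:
    """Hue angle of window-averaged chroma (Cb-128, Cr-128), valid-mode."""
    k = _gaussian_kernel(win, sigma)
    mcb = convolve2d(cb - 128.0, k, mode="valid")
    mcr = convolve2d(cr - 128.0, k, mode="valid")
    return np.arctan2(mcr, mcb)


def color_similarity(original: np.ndarray, processed: np.ndarray,
                     window: int = 11, sigma: float = 1.5
                     ) -> tuple[float, float, float]:
    """(SSIM, MSSIM, SHSIM) on the Cb/Cr chrominance planes.

    SSIM: global single-window similarity averaged over Cb and Cr.
    MSSIM: mean of the local 11x11 Gaussian-window similarity map, averaged
    over Cb and Cr.  SHSIM: mean over windows of the plane-averaged local
    similarity times the hue agreement ``1 - |dh|/pi``, with dh the wrapped
    difference of window-mean chroma angles.
    """
    original = as_rgb(original)
    processed = as_rgb(processed)
    _check_same_shape(original, processed)
    if min(original.shape[:2]) < window:
        raise ValueError(f"images must be at least {window} pixels per side")
    _, cb1, cr1 = rgb_to_ycbcr(original)
    _, cb2, cr2 = rgb_to_ycbcr(processed)

    ssim_val = 0.5 * (_ssim_global(cb1, cb2) + _ssim_global(cr1, cr2))
    map_cb = _ssim_map(cb1, cb2, window, sigma)
    map_cr = _ssim_map(cr1, cr2, window, sigma)
    mssim_val = 0.5 * (map_cb.mean() + map_cr.mean())

    h1 = _window_hue(cb1, cr1, window, sigma)
    h2 = _window_hue(cb2, cr2, window, sigma)
    dh = np.abs(np.angle(np.exp(1j * (h1 - h2))))
    hue_sim = 1.0 - dh / np.pi
    shsim_val = float(np.mean(0.5 * (map_cb + map_cr) * hue_sim))
    return float(ssim_val), float(mssim_val), shsim_val


def colorfulness(img: np.ndarray) -> float:
    """Opponent-channel colorfulness metric CM (0 for achromatic images)."""
    img = as_rgb(img).astype(np.float64)
    rg = img[..., 0] - img[..., 1]
    yb = 0.5 * (img[..., 0] + img[..., 1]) - img[..., 2]
    sigma = math.hypot(rg.std(), yb.std())
    mu = math.hypot(rg.mean(), yb.mean())
    return sigma + 0.3 * mu


def cef(original: np.ndarray, processed: np.ndarray) -> float:
    """Color enhancement factor ``CM(processed) / CM(original)``.

    An exactly achromatic original has CM = 0: the ratio is returned as
    ``inf`` when the processed image carries any chroma (unbounded
    enhancement) and NaN when both images are achromatic.
    """
    cm_o = colorfulness(original)
    cm_p = colorfulness(processed)
    if cm_o == 0:
        return math.inf if cm_p > 0 else math.nan
    return cm_p / cm_o


@dataclass
class MetricsReport:
    """Flat record of every quality number for an (original, processed) pair.

    Color-only fields are ``None`` (serialized as ``n/a``) for grayscale
    pairs; undefined statistics are NaN; infinite PSNR serializes as "inf".
    """

    psnr_db: float | None = None
    svr_contrast: float | None = None
    svr_intensity: float | None = None
    uiq: float | None = None
    cie94_delta_e: float | None = None
    ssim: float | None = None
    mssim: float | None = None
    shsim: float | None = None
    cef: float | None = None

    def to_dict(self) -> dict[str, str]:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None:
                out[f.name] = "n/a"
            elif isinstance(v, float) and math.isinf(v):
                out[f.name] = "inf"
            elif isinstance(v, float) and math.isnan(v):
                out[f.name] = "nan"
            else:
                out[f.name] = f"{v:.6f}"
        return out

    @staticmethod
    def csv_header() -> list[str]:
        return [f.name for f in fields(MetricsReport)]

    def csv_row(self) -> list[str]:
        d = self.to_dict()
        return [d[k] for k in self.csv_header()]


def evaluate_pair(original: np.ndarray, processed: np.ndarray,
                  colorized_original: np.ndarray | None = None) -> MetricsReport:
    """Populate a :class:`MetricsReport` for an image pair.

    Both images must share layout (both RGB or both grayscale) and shape.
    For RGB pairs the grayscale metrics are computed on the BT.601 luma of
    each image.  *colorized_original*, if given, supplies the reference for
    the luminance round-trip PSNR protocol: PSNR is then computed between
    ``original`` (grayscale) and the luma of ``colorized_original``.
    """
    report = MetricsReport()
    if np.ndim(original) != np.ndim(processed):
        raise ValueError("original and processed must both be RGB or both grayscale")
    if np.ndim(original) == 3:
        original = as_rgb(original)
        processed = as_rgb(processed)
        _check_same_shape(original, processed)
        y1, _, _ = rgb_to_ycbcr(original)
        y2, _, _ = rgb_to_ycbcr(processed)
        g1 = np.clip(np.rint(y1), 0, 255).astype(np.uint8)
        g2 = np.clip(np.rint(y2), 0, 255).astype(np.uint8)
        report.cie94_delta_e = cie94_delta_e(original, processed)
        s, ms, sh = color_similarity(original, processed)
        report.ssim, report.mssim, report.shsim = s, ms, sh
        report.cef = cef(original, processed)
    else:
        g1 = as_gray(original)
        g2 = as_gray(processed)
        _check_same_shape(g1, g2)
    report.psnr_db = psnr(g1, g2)
    report.svr_contrast, report.svr_intensity = svr_statistics(g1, g2)
    report.uiq = uiq(g1, g2)
    if colorized_original is not None:
        from .io import rgb_to_luminance
        regen = rgb_to_luminance(colorized_original)
        report.psnr_db = psnr(as_gray(original) if np.ndim(original) == 2 else g1,
                              regen)
    return report
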