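"""Dynamic luminance->RGB color map: build, fill, smooth, tone-map, apply.

The color map Z is a 256-row lookup table giving an (R, G, B) triplet for
each luminance value 0..255.  It is harvested from a *theme* image (a color
endoscopy frame from a nearby anatomical location): every theme pixel is
assigned to the bin of its luminance Y = R/4 + G/2 + B/4, colliding triplets
are averaged channel-wise, empty bins are filled by linear interpolation
between the nearest observed neighbors, and the table is smoothed per
channel to suppress ripple that would otherwise show up as color artifacts.
Rows 0 and 255 are pinned to full black and full white — they bound every
edge gap and survive smoothing.

Colorization is then a pure table lookup: each pixel of an (enhanced)
grayscale image is replaced by the map row at its luminance value.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator

from .io import as_gray, as_rgb, rgb_to_luminance

logger = logging.getLogger(__name__)

__all__ = [
    "ColorMap",
    "SmoothingSpec",
    "SMOOTHING_METHODS",
    "accumulate_bins",
    "average_collisions",
    "interpolate_gaps",
    "smooth_map",
    "build_color_map",
    "apply_color_map",
    "apply_tone_curve",
    "ThemeColorizer",
]

OBSERVED = "observed"
INTERPOLATED = "interpolated"
PINNED = "pinned"
EMPTY = "empty"

SMOOTHING_METHODS = (
    "moving_average",
    "linear_local_regression",
    "quadratic_local_regression",
    "savitzky_golay",
    "robust_linear_local_regression",
    "robust_quadratic_local_regression",
)

#: spans validated against the reference grid; other odd spans log a note
_STANDARD_SPANS = (5, 9, 15, 19)


class ColorMap:
    """256-row luminance -> (R, G, B) lookup table with row provenance.

    Rows are kept at float precision until application; a *finalized* map has
    no ``empty`` rows, row 0 = (0, 0, 0) and row 255 = (255, 255, 255), and
    all values within [0, 255].  Unobserved rows of a partial map hold NaN.
    """

    def __init__(self, rows: np.ndarray, provenance: np.ndarray | list[str]):
        rows = np.asarray(rows, dtype=np.float64)
        provenance = np.asarray(provenance, dtype=object)
        if rows.shape != (256, 3):
            raise ValueError(f"color map rows must be (256, 3), got {rows.shape}")
        if provenance.shape != (256,):
            raise ValueError("provenance must have 256 entries")
        observed = provenance != EMPTY
        vals = rows[observed]
        if np.any(np.isnan(vals)) or np.any(vals < 0) or np.any(vals > 255):
            raise ValueError("observed map values must lie in [0, 255]")
        self.rows = rows
        self.provenance = provenance

    @classmethod
    def empty(cls) -> "ColorMap":
        return cls(np.full((256, 3), np.nan), np.array([EMPTY] * 256, dtype=object))

    @property
    def is_complete(self) -> bool:
        return not np.any(self.provenance == EMPTY)

    def copy(self) -> "ColorMap":
        return ColorMap(self.rows.copy(), self.provenance.copy())

    def lookup_table(self) -> np.ndarray:
        """Quantized (256, 3) uint8 table for application."""
        if not self.is_complete:
            raise ValueError("cannot quantize a partial color map")
        return np.clip(np.rint(self.rows), 0, 255).astype(np.uint8)

    def validate_finalized(self) -> None:
        if not self.is_complete:
            raise ValueError("map has unfilled rows")
        if not np.array_equal(self.rows[0], [0.0, 0.0, 0.0]):
            raise ValueError("row 0 must be pinned to (0, 0, 0)")
        if not np.array_equal(self.rows[255], [255.0, 255.0, 255.0]):
            raise ValueError("row 255 must be pinned to (255, 255, 255)")

    # -- serialization: CSV with header Y,R,G,B,provenance ------------------
    def to_csv(self, path_or_buf) -> None:
        close = False
        if isinstance(path_or_buf, (str, os.PathLike)):
            fh = open(path_or_buf, "w", newline="")
            close = True
        else:
            fh = path_or_buf
        try:
            w = csv.writer(fh)
            w.writerow(["Y", "R", "G", "B", "provenance"])
            for y in range(256):
                r, g, b = self.rows[y]
                w.writerow([y, f"{r:.6f}", f"{g:.6f}", f"{b:.6f}",
                            self.provenance[y]])
        finally:
            if close:
                fh.close()

    @classmethod
    def from_csv(cls, path_or_buf) -> "ColorMap":
        close = False
        if isinstance(path_or_buf, (str, os.PathLike)):
            fh = open(path_or_buf, "r", newline="")
            close = True
        else:
            fh = path_or_buf
        try:
            reader = csv.reader(fh)
            header = next(reader)
            if [h.strip() for h in header[:4]] != ["Y", "R", "G", "B"]:
                raise ValueError("color map CSV must have header Y,R,G,B[,provenance]")
            rows = np.full((256, 3), np.nan)
            prov = np.array([EMPTY] * 256, dtype=object)
            for rec in reader:
                y = int(rec[0])
                rows[y] = [float(rec[1]), float(rec[2]), float(rec[3])]
                prov[y] = rec[4] if len(rec) > 4 else OBSERVED
            return cls(rows, prov)
        finally:
            if close:
                fh.close()

    def __repr__(self) -> str:  # pragma: no cover
        n_obs = int(np.sum(self.provenance == OBSERVED))
        return f"ColorMap(observed={n_obs}, complete={self.is_complete})"


@dataclass(frozen=True)
class SmoothingSpec:
    """Smoothing family and window span applied per channel to the map.

    The default, linear local regression with span 19, gives the best
    luminance round-trip fidelity among the six standard families on the
    reference grid of spans {5, 9, 15, 19}.
    """

    method: str = "linear_local_regression"
    span: int = 19

    def __post_init__(self) -> None:
        if self.method not in SMOOTHING_METHODS:
            raise ValueError(
                f"unknown smoothing method {self.method!r}; "
                f"valid methods: {', '.join(SMOOTHING_METHODS)}"
            )
        if self.span < 3 or self.span % 2 == 0:
            raise ValueError("span must be an odd integer >= 3")
        if self.span not in _STANDARD_SPANS:
            logger.info("span %d is outside the standard grid %s",
                        self.span, _STANDARD_SPANS)


def accumulate_bins(theme: np.ndarray) -> dict[int, np.ndarray]:
    """Assign every theme pixel to the bin of its luminance.

    Returns a mapping ``{Y: (n, 3) float array of RGB triplets}`` covering
    the non-empty bins; the total count over bins equals H*W.
    """
    theme = as_rgb(theme)
    if theme.size == 0:
        raise ValueError("theme image is empty")
    lum = rgb_to_luminance(theme).ravel()
    pix = theme.reshape(-1, 3).astype(np.float64)
    order = np.argsort(lum, kind="stable")
    lum_sorted = lum[order]
    pix_sorted = pix[order]
    bins: dict[int, np.ndarray] = {}
    values, starts = np.unique(lum_sorted, return_index=True)
    starts = list(starts) + [len(lum_sorted)]
    for i, y in enumerate(values):
        bins[int(y)] = pix_sorted[starts[i]:starts[i + 1]]
    return bins


def average_collisions(bins: dict[int, np.ndarray]) -> ColorMap:
    """Collapse each bin to the channel-wise mean of its triplets.

    The mean is kept at float precision; bins absent from the mapping are
    flagged ``empty`` in the returned partial map.
    """
    cmap = ColorMap.empty()
    for y, triplets in bins.items():
        triplets = np.atleast_2d(np.asarray(triplets, dtype=np.float64))
        cmap.rows[y] = triplets.mean(axis=0)
        cmap.provenance[y] = OBSERVED
    return cmap


def interpolate_gaps(partial: ColorMap, printed_form: bool = False) -> ColorMap:
    """Fill empty rows by straight-line interpolation between observed rows.

    Rows 0 and 255 are first pinned to black and white so every gap is
    bounded.  A run of ``d+1`` empty rows M..M+d between observed rows M-1
    and M+d+1 is filled channel-wise as

        X[M+i] = X[M-1] + (X[M+d+1] - X[M-1]) * (i+1) / (d+2)

    ``printed_form=True`` switches to the formula with the opposite sign on
    the slope term, kept only for auditing against the original description;
    it extrapolates away from the next observed entry and can leave [0, 255],
    so its output is clipped.
    """
    cmap = partial.copy()
    cmap.rows[0] = (0.0, 0.0, 0.0)
    cmap.rows[255] = (255.0, 255.0, 255.0)
    cmap.provenance[0] = PINNED
    cmap.provenance[255] = PINNED

    known = cmap.provenance != EMPTY
    idx = np.flatnonzero(known)
    missing = np.flatnonzero(~known)
    if missing.size == 0:
        return cmap

    if not printed_form:
        for c in range(3):
            cmap.rows[missing, c] = np.interp(missing, idx, cmap.rows[idx, c])
    else:
        # audit path: X[M+i] = X[M-1] + (X[M-1] - X[M+d+1])/(d+2) * (i+1)
        y = 1
        while y < 255:
            if known[y]:
                y += 1
                continue
            m = y
            while not known[y]:
                y += 1
            d = y - m - 1
            left = cmap.rows[m - 1]
            right = cmap.rows[m + d + 1]
            for i in range(d + 1):
                cmap.rows[m + i] = left + (left - right) / (d + 2) * (i + 1)
        cmap.rows = np.clip(cmap.rows, 0.0, 255.0)

    cmap.provenance[missing] = INTERPOLATED
    return cmap


# ---------------------------------------------------------------------------
# 1-D smoothers over the 256-entry table (MATLAB `smooth` conventions)

def _moving_average(y: np.ndarray, span: int) -> np.ndarray:
    """Centered moving average; the window shrinks symmetrically at the ends
    (so a straight line is reproduced exactly everywhere)."""
    n = len(y)
    half = span // 2
    c = np.concatenate([[0.0], np.cumsum(y)])
    out = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = (c[i + k + 1] - c[i - k]) / (2 * k + 1)
    return out


def _tricube(d: np.ndarray) -> np.ndarray:
    return np.clip(1.0 - np.abs(d) ** 3, 0.0, None) ** 3


def _local_regression(y: np.ndarray, span: int, degree: int,
                      robust: bool, iters: int = 5) -> np.ndarray:
    """Tricube-weighted local polynomial fit over the nearest-span window
    (LOWESS for degree 1, LOESS for degree 2); robust variants add bisquare
    re-weighting passes."""
    n = len(y)
    x = np.arange(n, dtype=np.float64)
    span = min(span, n)
    rw = np.ones(n)
    fitted = y.astype(np.float64).copy()
    passes = iters + 1 if robust else 1
    for _ in range(passes):
        for i in range(n):
            lo = max(0, min(i - span // 2, n - span))
            hi = lo + span
            xx = x[lo:hi] - i
            dmax = np.abs(xx).max()
            w = _tricube(xx / dmax) * rw[lo:hi]
            if w.sum() <= 0 or np.count_nonzero(w) <= degree:
                fitted[i] = y[i]
                continue
            coef = np.polynomial.polynomial.polyfit(
                xx, y[lo:hi], degree, w=np.sqrt(w))
            fitted[i] = coef[0]
        if robust:
            resid = y - fitted
            s = np.median(np.abs(resid))
            if s <= 0:
                break
            rw = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2
    return fitted


def _smooth_series(y: np.ndarray, spec: SmoothingSpec) -> np.ndarray:
    m, span = spec.method, spec.span
    if m == "moving_average":
        return _moving_average(y, span)
    if m == "savitzky_golay":
        return savgol_filter(y, span, polyorder=2, mode="interp")
    degree = 2 if "quadratic" in m else 1
    return _local_regression(y, span, degree, robust=m.startswith("robust"))


def smooth_map(cmap: ColorMap, spec: SmoothingSpec | None = None) -> ColorMap:
    """Smooth each channel of a complete map as a 1-D series over Y.

    After smoothing, rows 0 and 255 are re-pinned to black/white and values
    are clipped to [0, 255].
    """
    if not cmap.is_complete:
        raise ValueError("smooth_map requires a gap-free color map")
    spec = spec or SmoothingSpec()
    out = cmap.copy()
    for c in range(3):
        out.rows[:, c] = _smooth_series(cmap.rows[:, c], spec)
    out.rows = np.clip(out.rows, 0.0, 255.0)
    out.rows[0] = (0.0, 0.0, 0.0)
    out.rows[255] = (255.0, 255.0, 255.0)
    out.provenance[0] = PINNED
    out.provenance[255] = PINNED
    return out


def build_color_map(theme: np.ndarray, spec: SmoothingSpec | None = None,
                    printed_interpolation: bool = False) -> ColorMap:
    """Full map construction: bin -> average -> interpolate -> smooth."""
    bins = accumulate_bins(theme)
    partial = average_collisions(bins)
    filled = interpolate_gaps(partial, printed_form=printed_interpolation)
    final = smooth_map(filled, spec)
    final.validate_finalized()
    return final


def apply_color_map(img: np.ndarray, cmap: ColorMap) -> np.ndarray:
    """Colorize a grayscale image by pure table lookup (no blending)."""
    img = as_gray(img)
    return cmap.lookup_table()[img]


def load_tone_curve(path_or_buf) -> np.ndarray:
    """Read a tone curve CSV: header Y,R,G,B (256 rows) or a single shared
    column; returns a (256, 3) float array."""
    close = False
    if isinstance(path_or_buf, (str, os.PathLike)):
        fh = open(path_or_buf, "r", newline="")
        close = True
    else:
        fh = path_or_buf
    try:
        reader = csv.reader(fh)
        header = next(reader)
        records = [rec for rec in reader if rec]
    finally:
        if close:
            fh.close()
    if len(records) != 256:
        raise ValueError(f"tone curve must have 256 rows, got {len(records)}")
    if len(header) >= 4:
        curve = np.array([[float(v) for v in rec[1:4]] for rec in records])
    else:
        col = np.array([float(rec[-1]) for rec in records])
        curve = np.stack([col] * 3, axis=1)
    return curve


def apply_tone_curve(cmap: ColorMap, curve: np.ndarray) -> ColorMap:
    """Transform each map row channel-wise through a 256-entry tone curve.

    ``curve`` is (256,) shared across channels or (256, 3) per channel, with
    values in [0, 255]; non-integer map values are sent through the curve by
    linear interpolation.  Endpoints are re-pinned afterwards.
    """
    curve = np.asarray(curve, dtype=np.float64)
    if curve.ndim == 1:
        curve = np.stack([curve] * 3, axis=1)
    if curve.shape != (256, 3):
        raise ValueError(f"tone curve must have 256 entries per channel, "
                         f"got shape {curve.shape}")
    if np.any(curve < 0) or np.any(curve > 255):
        raise ValueError("tone curve values must lie in [0, 255]")
    out = cmap.copy()
    grid = np.arange(256, dtype=np.float64)
    for c in range(3):
        out.rows[:, c] = np.interp(cmap.rows[:, c], grid, curve[:, c])
    out.rows[0] = (0.0, 0.0, 0.0)
    out.rows[255] = (255.0, 255.0, 255.0)
    out.provenance[0] = PINNED
    out.provenance[255] = PINNED
    return out


class ThemeColorizer(BaseEstimator):
    """Luminance-indexed colorizer fitted on a theme image.

    ``fit`` harvests the 256-entry luminance->RGB dictionary from a color
    theme image; ``transform`` colorizes a grayscale image by table lookup.

    Parameters
    ----------
    smoothing_method : str, default="linear_local_regression"
        One of the six supported table smoothers.
    span : int, default=19
        Odd smoothing window width in table rows.
    tone_curve : ndarray of shape (256,) or (256, 3), optional
        Transfer curve applied to the fitted map (virtual-chromoendoscopy
        style tone enhancement).
    printed_interpolation : bool, default=False
        Audit flag selecting the sign-flipped gap-filling formula.

    Attributes
    ----------
    color_map_ : ColorMap
        Finalized lookup table after fitting.
    n_observed_bins_ : int
        Number of luminance bins observed in the theme image.

    Examples
    --------
    >>> import numpy as np
    >>> from endocolor.colormap import ThemeColorizer
    >>> ramp = np.repeat(np.arange(256, dtype=np.uint8)[None, :], 8, axis=0)
    >>> theme = np.stack([ramp] * 3, axis=-1)       # achromatic ramp theme
    >>> col = ThemeColorizer().fit(theme)
    >>> out = col.transform(ramp)
    >>> bool(np.all(np.abs(out.astype(int) - ramp[..., None].astype(int)) <= 1))
    True
    """

    def __init__(self, smoothing_method: str = "linear_local_regression",
                 span: int = 19, tone_curve: np.ndarray | None = None,
                 printed_interpolation: bool = False):
        self.smoothing_method = smoothing_method
        self.span = span
        self.tone_curve = tone_curve
        self.printed_interpolation = printed_interpolation

    def fit(self, X: np.ndarray, y=None):
        """Build the color map from theme image *X* ((H, W, 3) uint8)."""
        spec = SmoothingSpec(self.smoothing_method, self.span)
        cmap = build_color_map(X, spec,
                               printed_interpolation=self.printed_interpolation)
        self.n_observed_bins_ = int(np.sum(
            np.asarray(cmap.provenance) == OBSERVED))
        if self.tone_curve is not None:
            cmap = apply_tone_curve(cmap, self.tone_curve)
        self.color_map_ = cmap
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Colorize grayscale image *X* through the fitted lookup table."""
        if not hasattr(self, "color_map_"):
            raise ValueError("ThemeColorizer is not fitted; call fit(theme) first")
        return apply_color_map(X, self.color_map_)

    def fit_transform(self, X: np.ndarray, y=None, **fit_params):
        raise TypeError(
            "fit takes a theme image and transform a grayscale image; "
            "call them separately")
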