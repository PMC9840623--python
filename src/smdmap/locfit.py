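"""Single-molecule spot detection, Gaussian fitting and drift correction.

Spots are detected per frame with a difference-of-Gaussians bandpass and a
local-maximum threshold in noise-SD units, then fit with an elliptical 2D
Gaussian

    f(x, y) = B + A exp(-[(x-x0)^2 / (2 sx^2) + (y-y0)^2 / (2 sy^2)])

by least squares (Levenberg-Marquardt-type trust region). Lateral drift is
estimated fiducial-free by redundant cross-correlation of super-resolved 2D
histograms of temporal segments and removed by subtraction.

Coordinate convention: tables are in nm with the origin at the field's
top-left corner; pixel (i, j) spans [j*p, (j+1)*p) x [i*p, (i+1)*p) nm so a
localization at a pixel's center has coordinate (index + 0.5) * pixel_size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from skimage.feature import peak_local_max
from skimage.filters import difference_of_gaussians
from skimage.registration import phase_cross_correlation

__all__ = [
    "GaussianSpotFit",
    "DriftSeries",
    "fit_gaussian_spot",
    "localize_stack",
    "estimate_and_apply_drift",
]


@dataclass
class GaussianSpotFit:
    """Parameters of one elliptical 2D Gaussian spot (lengths in nm)."""

    B: float
    A: float
    x0: float
    y0: float
    sigma_x: float
    sigma_y: float
    residual_norm: float = np.nan
    converged: bool = False
    rejected: bool = False
    reason: str = ""


@dataclass
class DriftSeries:
    """Per-segment lateral drift with linear interpolation between centers.

    The reference (first) segment has drift (0, 0) by construction.
    """

    segment_frames: np.ndarray   # (n_seg, 2) inclusive frame ranges
    dx_nm: np.ndarray
    dy_nm: np.ndarray
    interpolation: str = "piecewise-linear"

    def at_frames(self, frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        centers = self.segment_frames.mean(axis=1)
        if len(centers) == 1:
            z = np.zeros(np.shape(frames))
            return z + self.dx_nm[0], z + self.dy_nm[0]

        def interp_extrap(v):
            out = np.interp(frames, centers, v)
            lo = frames < centers[0]
            hi = frames > centers[-1]
            sl0 = (v[1] - v[0]) / (centers[1] - centers[0])
            sl1 = (v[-1] - v[-2]) / (centers[-1] - centers[-2])
            out = np.where(lo, v[0] + sl0 * (frames - centers[0]), out)
            out = np.where(hi, v[-1] + sl1 * (frames - centers[-1]), out)
            return out

        return interp_extrap(self.dx_nm), interp_extrap(self.dy_nm)


# ---------------------------------------------------------------------------
# spot fitting
# ---------------------------------------------------------------------------

def _gauss2d(params, xg, yg):
    B, A, x0, y0, sx, sy = params
    return B + A * np.exp(-((xg - x0) ** 2 / (2 * sx ** 2) +
                            (yg - y0) ** 2 / (2 * sy ** 2)))


def fit_gaussian_spot(
    roi: np.ndarray,
    pixel_size_nm: float = 100.0,
    origin_nm: tuple[float, float] = (0.0, 0.0),
    init: GaussianSpotFit | None = None,
    sigma_bounds_nm: tuple[float, float] = (40.0, 500.0),
    min_amplitude: float = 1e-3,
) -> GaussianSpotFit:
    """Least-squares elliptical Gaussian fit of one candidate ROI.

    ``roi`` is a small image patch (>= 7x7 pixels); ``origin_nm`` is the
    world coordinate of its top-left corner. The initializer defaults to
    peak/median heuristics. Fits are rejected (``rejected=True`` with a
    reason code) on no signal, non-convergence, a center outside the ROI, or
    a sigma pinned at its bound.
    """
    roi = np.asarray(roi, float)
    if roi.shape[0] < 7 or roi.shape[1] < 7:
        raise ValueError("roi must be at least 7x7 pixels")
    h, w = roi.shape
    ys, xs = np.mgrid[0:h, 0:w]
    xg = origin_nm[0] + (xs + 0.5) * pixel_size_nm
    yg = origin_nm[1] + (ys + 0.5) * pixel_size_nm

    B0 = float(np.median(roi))
    A0 = float(roi.max() - B0)
    if init is None:
        iy, ix = np.unravel_index(np.argmax(roi), roi.shape)
        init = GaussianSpotFit(B=B0, A=max(A0, min_amplitude),
                               x0=float(xg[iy, ix]), y0=float(yg[iy, ix]),
                               sigma_x=130.0, sigma_y=130.0)
    if A0 <= min_amplitude:
        return GaussianSpotFit(B0, A0, init.x0, init.y0, init.sigma_x,
                               init.sigma_y, rejected=True, reason="no signal")

    p0 = [init.B, init.A, init.x0, init.y0, init.sigma_x, init.sigma_y]
    lo = [-np.inf, 0.0, xg.min(), yg.min(), sigma_bounds_nm[0], sigma_bounds_nm[0]]
    hi = [np.inf, np.inf, xg.max(), yg.max(), sigma_bounds_nm[1], sigma_bounds_nm[1]]
    p0 = np.clip(p0, lo, hi)

    res = least_squares(
        lambda p: (_gauss2d(p, xg, yg) - roi).ravel(), p0,
        bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    B, A, x0, y0, sx, sy = res.x
    fit = GaussianSpotFit(float(B), float(A), float(x0), float(y0),
                          float(sx), float(sy),
                          residual_norm=float(np.linalg.norm(res.fun)),
                          converged=bool(res.success))
    tol = 1e-6 * pixel_size_nm
    if not res.success:
        fit.rejected, fit.reason = True, "did not converge"
    elif not (xg.min() + tol < x0 < xg.max() - tol and
              yg.min() + tol < y0 < yg.max() - tol):
        fit.rejected, fit.reason = True, "center outside roi"
    elif min(sx, sy) <= sigma_bounds_nm[0] * 1.001 or \
            max(sx, sy) >= sigma_bounds_nm[1] * 0.999:
        fit.rejected, fit.reason = True, "sigma at bound"
    elif A <= min_amplitude:
        fit.rejected, fit.reason = True, "no signal"
    return fit


# ---------------------------------------------------------------------------
# stack localization
# ---------------------------------------------------------------------------

def localize_stack(
    stack: np.ndarray,
    pixel_size_nm: float = 100.0,
    threshold_sd: float = 4.0,
    roi_half: int = 4,
    psf_sigma_nm: float = 130.0,
    sigma_bounds_nm: tuple[float, float] = (40.0, 500.0),
) -> pd.DataFrame:
    """Detect and fit single-molecule spots in every frame of a stack.

    Detection: difference-of-Gaussians bandpass tuned to the PSF scale,
    candidate pixels are local maxima above ``threshold_sd`` times a robust
    (MAD) noise estimate of the bandpassed frame. Candidate pairs closer
    than 2 * psf_sigma are both discarded (overlap policy) rather than risk
    a merged midpoint fit. Accepted fits become one table row each, frames
    1-based, positions in nm.
    """
    stack = np.asarray(stack, float)
    if stack.ndim == 2:
        stack = stack[None]
    rows = []
    s_px = psf_sigma_nm / pixel_size_nm
    for fi, frame in enumerate(stack, start=1):
        dog = difference_of_gaussians(frame, 0.6 * s_px, 1.8 * s_px)
        mad = np.median(np.abs(dog - np.median(dog)))
        noise_sd = 1.4826 * mad
        thr = threshold_sd * noise_sd
        if thr <= 0:
            thr = 1e-6 * (np.ptp(dog) if np.ptp(dog) > 0 else 1.0)
            if np.ptp(dog) == 0:
                continue
        peaks = peak_local_max(dog, min_distance=1,
                               threshold_abs=thr, exclude_border=False)
        if peaks.size == 0:
            continue
        # merge plateau twins: adjacent peaks with exactly tied DoG values
        # (an emitter sitting on a pixel boundary, noiseless data)
        vals = dog[peaks[:, 0], peaks[:, 1]]
        tie_tol = 1e-9 * max(np.ptp(dog), 1.0)
        merged = np.ones(len(peaks), bool)
        for i in range(len(peaks)):
            if not merged[i]:
                continue
            for j in range(i + 1, len(peaks)):
                if merged[j] and np.sum((peaks[i] - peaks[j]) ** 2) <= 2 \
                        and abs(vals[i] - vals[j]) <= tie_tol:
                    merged[j] = False
        peaks, vals = peaks[merged], vals[merged]
        # overlap policy: reject both members of any too-close pair
        keep = np.ones(len(peaks), bool)
        min_sep_px = 2.0 * s_px
        d2 = np.sum((peaks[:, None, :] - peaks[None, :, :]) ** 2, axis=-1)
        close = (d2 < min_sep_px ** 2) & ~np.eye(len(peaks), dtype=bool)
        keep[np.any(close, axis=1)] = False

        for (py, px), ok in zip(peaks, keep):
            if not ok:
                continue
            y0, y1 = py - roi_half, py + roi_half + 1
            x0, x1 = px - roi_half, px + roi_half + 1
            if y0 < 0 or x0 < 0 or y1 > frame.shape[0] or x1 > frame.shape[1]:
                continue
            fit = fit_gaussian_spot(
                frame[y0:y1, x0:x1], pixel_size_nm,
                origin_nm=(x0 * pixel_size_nm, y0 * pixel_size_nm),
                sigma_bounds_nm=sigma_bounds_nm,
            )
            if fit.rejected:
                continue
            # PSF-consistency window: a pixel-sampled single emitter fits at
            # sigma ~ sqrt(psf^2 + px^2/12); a blended double inflates it
            sigma_exp = np.hypot(psf_sigma_nm, pixel_size_nm / np.sqrt(12.0))
            if not (0.7 * sigma_exp <= fit.sigma_x <= 1.12 * sigma_exp and
                    0.7 * sigma_exp <= fit.sigma_y <= 1.12 * sigma_exp):
                continue
            rows.append((fi, fit.x0, fit.y0, fit.A, fit.B,
                         fit.sigma_x, fit.sigma_y))
    return pd.DataFrame(rows, columns=[
        "frame", "x_nm", "y_nm", "amplitude", "background",
        "sigma_x_nm", "sigma_y_nm"])


# ---------------------------------------------------------------------------
# drift correction
# ---------------------------------------------------------------------------

def estimate_and_apply_drift(
    table: pd.DataFrame,
    segment_len_frames: int = 2000,
    bin_nm: float = 20.0,
    min_locs_per_segment: int = 50,
    upsample: int = 10,
) -> tuple[pd.DataFrame, DriftSeries]:
    """Fiducial-free lateral drift correction by redundant cross-correlation.

    The table is split into temporal segments of ``segment_len_frames``;
    each segment is rendered as a 2D histogram at ``bin_nm`` resolution and
    all segment pairs are registered by subpixel phase correlation. The
    per-segment drifts are the least-squares solution of the redundant
    pairwise shifts, anchored at zero for the first segment, interpolated
    piecewise-linearly over frames and subtracted. The correction is
    invertible: adding the returned series back restores the input.
    """
    frames = table["frame"].to_numpy()
    fmin, fmax = int(frames.min()), int(frames.max())
    n_seg = max(int(np.ceil((fmax - fmin + 1) / segment_len_frames)), 1)
    if n_seg < 2:
        warnings.warn("table spans a single drift segment; no correction applied")
        seg = np.array([[fmin, fmax]])
        return table.copy(), DriftSeries(seg, np.zeros(1), np.zeros(1))

    seg_ranges = np.array([
        [fmin + i * segment_len_frames,
         min(fmin + (i + 1) * segment_len_frames - 1, fmax)]
        for i in range(n_seg)])
    seg_of = np.clip((frames - fmin) // segment_len_frames, 0, n_seg - 1)

    x = table["x_nm"].to_numpy(float)
    y = table["y_nm"].to_numpy(float)
    pad = 4 * bin_nm
    xedges = np.arange(x.min() - pad, x.max() + pad + bin_nm, bin_nm)
    yedges = np.arange(y.min() - pad, y.max() + pad + bin_nm, bin_nm)

    hists = []
    for i in range(n_seg):
        sel = seg_of == i
        if sel.sum() < min_locs_per_segment:
            hists.append(None)
            continue
        h, _, _ = np.histogram2d(y[sel], x[sel], bins=[yedges, xedges])
        hists.append(h)
    if sum(h is not None for h in hists) < 2:
        warnings.warn("too few localizations per segment; identity drift")
        return table.copy(), DriftSeries(seg_ranges, np.zeros(n_seg),
                                         np.zeros(n_seg))

    # redundant pairwise registration, least-squares solve (anchor seg 0)
    rows_A, rhs_dx, rhs_dy = [], [], []
    idx_ok = [i for i, h in enumerate(hists) if h is not None]
    for ai in range(len(idx_ok)):
        for bi in range(ai + 1, len(idx_ok)):
            i, j = idx_ok[ai], idx_ok[bi]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                shift, _, _ = phase_cross_correlation(
                    hists[i], hists[j], upsample_factor=upsample,
                    normalization=None)
            row = np.zeros(n_seg)
            row[j], row[i] = 1.0, -1.0
            rows_A.append(row)
            # phase correlation returns the shift that registers segment j
            # onto segment i, i.e. minus the drift accrued between them
            rhs_dy.append(-shift[0] * bin_nm)
            rhs_dx.append(-shift[1] * bin_nm)
    A = np.vstack(rows_A + [np.eye(n_seg)[0][None, :] * 1e3])
    dx = np.linalg.lstsq(A, np.r_[rhs_dx, 0.0], rcond=None)[0]
    dy = np.linalg.lstsq(A, np.r_[rhs_dy, 0.0], rcond=None)[0]

    series = DriftSeries(seg_ranges, dx, dy)
    ddx, ddy = series.at_frames(frames)
    out = table.copy()
    out["x_nm"] = x - ddx
    out["y_nm"] = y - ddy
    return out, series
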