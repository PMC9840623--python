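"""Single-molecule displacement mapping (SMdM) core analysis.

Pairs localizations across stroboscopic frame pairs, models the pooled
displacement-length distribution as a truncated mixture of 2D random-walk
(Rayleigh) components plus a linear background term, fits it by maximum
likelihood, and reconstructs per-pixel diffusivity maps.

Model
-----
For isotropic 2D Brownian motion with diffusion coefficient ``D`` observed
over a fixed interval ``dt``, the displacement length ``r`` follows a
Rayleigh density

    P(r) = (2 r / (4 D dt)) * exp(-r^2 / (4 D dt)).

False pairings of a molecule with unrelated nearby localizations occur with
probability growing linearly in ``r`` (uniform spatial background), adding a
``b * r`` term. Because pairing is restricted to ``r <= r_max``, the density
is renormalized on [0, r_max]. With ``N`` diffusive components of fractions
``f_i`` (sum to 1) the full density is

                sum_i f_i (2r / s_i) exp(-r^2 / s_i) + b r
    P(r) = ---------------------------------------------------- ,
            1 - sum_i f_i exp(-r_max^2 / s_i) + (b/2) r_max^2

with ``s_i = 4 D_i dt``. The denominator is exactly the integral of the
numerator over [0, r_max], so the density always integrates to 1.

Units: positions and ``r`` in nm, ``dt`` in ms, ``D`` in um^2/s
(1 um^2/s = 1000 nm^2/ms; the conversion is applied in one place,
:data:`NM2_PER_MS_PER_UM2_S`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial import cKDTree

__all__ = [
    "DisplacementSet",
    "FitResult",
    "DiffusionMap",
    "extract_displacements",
    "displacement_pdf",
    "fit_displacement_mle",
    "closed_form_diffusion",
    "build_diffusion_map",
]

#: nm^2/ms per um^2/s — the single place the D unit conversion lives.
NM2_PER_MS_PER_UM2_S = 1.0e3

MIN_FIT_DISPLACEMENTS = 50


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DisplacementSet:
    """Paired-peak displacements with their fixed interval and cutoff.

    Endpoint coordinates are in nm; ``dt_ms`` is the peak-to-peak interval;
    ``r_max_nm`` the pairing search radius. ``pair_index`` is the frame-pair
    ordinal each record came from.
    """

    x0: np.ndarray
    y0: np.ndarray
    x1: np.ndarray
    y1: np.ndarray
    pair_index: np.ndarray
    dt_ms: float
    r_max_nm: float
    region: str = "all"

    def __post_init__(self) -> None:
        for name in ("x0", "y0", "x1", "y1", "pair_index"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        r = self.r
        if r.size and (r.max() > self.r_max_nm * (1 + 1e-12)):
            raise ValueError("displacement exceeds r_max_nm")

    @property
    def r(self) -> np.ndarray:
        """Euclidean displacement lengths in nm."""
        return np.hypot(self.x1 - self.x0, self.y1 - self.y0)

    def __len__(self) -> int:
        return int(self.x0.size)

    def subset(self, mask: np.ndarray, region: str | None = None) -> "DisplacementSet":
        return DisplacementSet(
            self.x0[mask], self.y0[mask], self.x1[mask], self.y1[mask],
            self.pair_index[mask], self.dt_ms, self.r_max_nm,
            region if region is not None else self.region,
        )

    def transformed(self, fn) -> "DisplacementSet":
        """Apply an (x, y) -> (x', y') coordinate map to both endpoints."""
        x0, y0 = fn(self.x0, self.y0)
        x1, y1 = fn(self.x1, self.y1)
        return DisplacementSet(x0, y0, x1, y1, self.pair_index,
                               self.dt_ms, self.r_max_nm, self.region)


@dataclass
class FitResult:
    """Maximum-likelihood fit of the displacement model.

    ``components`` is a list of (D_i in um^2/s, f_i) sorted by descending D;
    ``b`` is the background slope in 1/nm^2.
    """

    components: list[tuple[float, float]]
    b: float
    n_components: int
    log_likelihood: float
    n_displacements: int
    converged: bool
    message: str = ""
    n_starts: int = 0

    @property
    def D(self) -> list[float]:
        return [c[0] for c in self.components]

    @property
    def fractions(self) -> list[float]:
        return [c[1] for c in self.components]

    def to_dict(self) -> dict:
        return {
            "D": self.D,
            "f": self.fractions,
            "b": self.b,
            "loglik": self.log_likelihood,
            "n": self.n_displacements,
            "n_components": self.n_components,
            "converged": self.converged,
        }


@dataclass
class DiffusionMap:
    """Per-pixel local diffusivity on a square grid in the aligned cell frame.

    ``D`` holds the fitted diffusion coefficient (um^2/s) with NaN where the
    pixel has fewer than ``min_count`` displacements; ``counts`` is the
    per-pixel displacement count; ``origin_nm`` the (x, y) of the grid's
    low corner.
    """

    D: np.ndarray
    counts: np.ndarray
    origin_nm: tuple[float, float]
    pixel_nm: float
    min_count: int

    @property
    def valid_mask(self) -> np.ndarray:
        return self.counts >= self.min_count


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def extract_displacements(
    table: pd.DataFrame,
    dt_ms: float,
    r_max_nm: float = 600.0,
    nearest_only: bool = False,
) -> DisplacementSet:
    """Pair localizations across stroboscopic frame pairs.

    Frames are 1-based; pair ``k`` consists of frames ``(2k-1, 2k)`` — the
    excitation pulses sit at the end of the odd frame and the start of the
    following even frame, ``dt_ms`` apart. Every localization in the second
    frame within ``r_max_nm`` of a first-frame localization yields one
    displacement record (all candidates are retained; the ``b*r`` background
    term of the model absorbs the false pairs). With ``nearest_only=True``
    only the closest second-frame candidate is kept, for sensitivity
    analysis.
    """
    frames = table["frame"].to_numpy()
    x = table["x_nm"].to_numpy(float)
    y = table["y_nm"].to_numpy(float)

    odd = frames % 2 == 1
    out_x0, out_y0, out_x1, out_y1, out_k = [], [], [], [], []

    # group row indices by frame
    order = np.argsort(frames, kind="stable")
    sorted_frames = frames[order]
    uniq, starts = np.unique(sorted_frames, return_index=True)
    groups = {f: order[s:e] for f, s, e in
              zip(uniq, starts, list(starts[1:]) + [len(order)])}

    for f in uniq:
        if f % 2 == 0:
            continue
        i0 = groups[f]
        i1 = groups.get(f + 1)
        if i1 is None or i0.size == 0 or i1.size == 0:
            continue
        tree = cKDTree(np.column_stack([x[i1], y[i1]]))
        if nearest_only:
            d, j = tree.query(np.column_stack([x[i0], y[i0]]),
                              distance_upper_bound=r_max_nm)
            ok = np.isfinite(d)
            a, bidx = np.nonzero(ok)[0], j[ok]
        else:
            pairs = tree.query_ball_point(
                np.column_stack([x[i0], y[i0]]), r_max_nm)
            a = np.repeat(np.arange(i0.size), [len(p) for p in pairs])
            bidx = np.concatenate([np.asarray(p, int) for p in pairs]) \
                if a.size else np.empty(0, int)
        k = (f + 1) // 2
        out_x0.append(x[i0][a]); out_y0.append(y[i0][a])
        out_x1.append(x[i1][bidx]); out_y1.append(y[i1][bidx])
        out_k.append(np.full(a.size, k, int))

    if out_x0:
        cat = [np.concatenate(v) for v in (out_x0, out_y0, out_x1, out_y1, out_k)]
    else:
        cat = [np.empty(0), np.empty(0), np.empty(0), np.empty(0),
               np.empty(0, int)]
    return DisplacementSet(*cat, dt_ms=dt_ms, r_max_nm=r_max_nm)


# ---------------------------------------------------------------------------
# probability model
# ---------------------------------------------------------------------------

def _scales_nm2(D: np.ndarray, dt_ms: float) -> np.ndarray:
    """s_i = 4 D_i dt in nm^2."""
    return 4.0 * np.asarray(D, float) * NM2_PER_MS_PER_UM2_S * dt_ms


def _numerator(r: np.ndarray, D: np.ndarray, f: np.ndarray,
               b: float, dt_ms: float) -> np.ndarray:
    s = _scales_nm2(D, dt_ms)
    rr = np.atleast_1d(np.asarray(r, float))[:, None]
    mix = np.sum(f / s * 2.0 * rr * np.exp(-(rr ** 2) / s), axis=1)
    return mix + b * rr[:, 0]


def _denominator(D: np.ndarray, f: np.ndarray, b: float,
                 dt_ms: float, r_max_nm: float) -> float:
    s = _scales_nm2(D, dt_ms)
    if np.isinf(r_max_nm):
        if b != 0:
            raise ValueError("b must be 0 for an untruncated model")
        return 1.0
    trunc = float(np.sum(f * np.exp(-(r_max_nm ** 2) / s)))
    return 1.0 - trunc + 0.5 * b * r_max_nm ** 2


def displacement_pdf(
    r,
    components: Sequence[tuple[float, float]],
    b: float,
    r_max_nm: float,
    dt_ms: float,
):
    """Evaluate the truncated mixed-Rayleigh-plus-background density (1/nm).

    ``components`` is a sequence of (D_i in um^2/s, f_i); fractions must sum
    to 1. Defined on 0 <= r <= r_max only. With a single component, b = 0 and
    r_max = inf this reduces to the plain Rayleigh step-length density.
    """
    D = np.array([c[0] for c in components], float)
    f = np.array([c[1] for c in components], float)
    if np.any(D <= 0):
        raise ValueError("all D_i must be positive")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if b < 0:
        raise ValueError("b must be non-negative")
    rr = np.asarray(r, float)
    if np.any(rr < 0) or np.any(rr > r_max_nm * (1 + 1e-12)):
        raise ValueError("r outside [0, r_max]")
    out = _numerator(rr, D, f, b, dt_ms) / _denominator(D, f, b, dt_ms, r_max_nm)
    return out if np.ndim(r) else float(out[0])


# ---------------------------------------------------------------------------
# maximum likelihood fitting
# ---------------------------------------------------------------------------

def _sticks_to_fractions(logits: np.ndarray) -> np.ndarray:
    """Stick-breaking map from N-1 unconstrained logits to an N-simplex."""
    f = []
    rem = 1.0
    for z in logits:
        p = 1.0 / (1.0 + np.exp(-z))
        f.append(rem * p)
        rem *= 1.0 - p
    f.append(rem)
    return np.asarray(f)


def _fractions_to_sticks(f: np.ndarray) -> np.ndarray:
    logits = []
    rem = 1.0
    for fi in f[:-1]:
        p = np.clip(fi / max(rem, 1e-12), 1e-9, 1 - 1e-9)
        logits.append(np.log(p / (1 - p)))
        rem -= fi
    return np.asarray(logits)


def _neg_loglik(theta, r, n_comp, dt_ms, r_max_nm, beta_fixed):
    D = np.exp(theta[:n_comp])
    f = _sticks_to_fractions(theta[n_comp:2 * n_comp - 1])
    beta = beta_fixed if beta_fixed is not None else theta[-1]
    b = 0.0 if np.isinf(r_max_nm) else 2.0 * beta / r_max_nm ** 2
    num = _numerator(r, D, f, b, dt_ms)
    if np.any(num <= 0) or not np.all(np.isfinite(num)):
        return 1e30
    den = _denominator(D, f, b, dt_ms, r_max_nm)
    return float(-(np.sum(np.log(num)) - r.size * np.log(den)))


def _moment_D(r: np.ndarray, dt_ms: float) -> float:
    """Method-of-moments D from mean r^2 = 4 D dt (um^2/s)."""
    return float(np.mean(r ** 2) / (4.0 * dt_ms * NM2_PER_MS_PER_UM2_S))


def _initial_guesses(r: np.ndarray, n_comp: int, dt_ms: float):
    """Deterministic multistart grid: moments + quantile splits."""
    d_mom = max(_moment_D(r, dt_ms), 1e-5)
    guesses: list[tuple[np.ndarray, np.ndarray]] = []
    if n_comp == 1:
        for scale in (1.0, 0.5, 2.0):
            guesses.append((np.array([d_mom * scale]), np.array([1.0])))
    elif n_comp == 2:
        med = np.median(r)
        hi, lo = r[r >= med], r[r < med]
        d_hi = max(_moment_D(hi, dt_ms), 2e-5) if hi.size else d_mom * 3
        d_lo = max(_moment_D(lo, dt_ms), 1e-5) if lo.size else d_mom / 3
        if d_hi / max(d_lo, 1e-12) < 2:
            d_hi, d_lo = d_mom * 3, d_mom / 3
        for (a, c, f1) in ((d_hi, d_lo, 0.5), (d_mom * 5, d_mom * 0.1, 0.5),
                           (d_mom * 2, d_mom * 0.5, 0.7),
                           (d_mom * 10, d_mom * 0.05, 0.3)):
            guesses.append((np.array([a, c]), np.array([f1, 1 - f1])))
    else:
        qs = np.quantile(r, [1 / 3, 2 / 3])
        parts = [r[r < qs[0]], r[(r >= qs[0]) & (r < qs[1])], r[r >= qs[1]]]
        ds = sorted(
            (max(_moment_D(p, dt_ms), 1e-5) if p.size else d_mom for p in parts),
            reverse=True)
        guesses.append((np.array(ds), np.full(3, 1 / 3)))
        guesses.append((np.array([d_mom * 10, d_mom, d_mom * 0.1]),
                        np.full(3, 1 / 3)))
    return guesses


def _fit_mixture(
    r: np.ndarray,
    dt_ms: float,
    r_max_nm: float,
    n_components: int,
    fix_b: float | None,
) -> FitResult:
    """Shared MLE engine for the truncated and untruncated mixture models."""
    r = np.asarray(r, float)
    if np.isinf(r_max_nm) and fix_b not in (0, 0.0):
        raise ValueError("untruncated model requires b fixed at 0")

    beta_starts: tuple[float, ...]
    if fix_b is not None:
        beta_fixed = 0.0 if np.isinf(r_max_nm) else 0.5 * fix_b * r_max_nm ** 2
        beta_starts = ()
    else:
        beta_fixed = None
        beta_starts = (0.01, 0.3)

    n = n_components
    bounds = [(np.log(1e-6), np.log(1e5))] * n + [(-14.0, 14.0)] * (n - 1)
    if beta_fixed is None:
        bounds += [(0.0, 1e4)]

    best = None
    n_starts = 0
    for D0, f0 in _initial_guesses(r, n, dt_ms):
        for beta0 in (beta_starts or (None,)):
            theta0 = np.concatenate([
                np.log(np.clip(D0, 1e-6, 1e5)),
                _fractions_to_sticks(f0),
                [] if beta0 is None else [beta0],
            ])
            res = minimize(
                _neg_loglik, theta0,
                args=(r, n, dt_ms, r_max_nm, beta_fixed),
                method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
            )
            n_starts += 1
            if best is None or res.fun < best.fun - 1e-9:
                best = res

    theta = best.x
    D = np.exp(theta[:n])
    f = _sticks_to_fractions(theta[n:2 * n - 1])
    beta = beta_fixed if beta_fixed is not None else float(theta[-1])
    b = 0.0 if np.isinf(r_max_nm) else 2.0 * beta / r_max_nm ** 2
    order = np.argsort(-D)
    comps = [(float(D[i]), float(f[i])) for i in order]
    return FitResult(
        components=comps,
        b=float(b),
        n_components=n,
        log_likelihood=float(-best.fun),
        n_displacements=int(r.size),
        converged=bool(best.success),
        message=str(best.message),
        n_starts=n_starts,
    )


def fit_displacement_mle(
    ds: DisplacementSet,
    n_components: int = 1,
    fix_b: float | None = None,
) -> FitResult:
    """Fit the displacement set by maximum likelihood.

    Maximizes the summed log density of the truncated mixture model over
    {D_i, f_i, b} subject to sum f_i = 1, D_i > 0, b >= 0. The optimizer is
    a bounded quasi-Newton on transformed parameters (log D_i, stick-breaking
    fractions, dimensionless background weight), started from a deterministic
    multistart grid (method of moments and quantile splits); ties resolve to
    the highest log-likelihood. Pass ``fix_b`` to pin the background slope
    (``fix_b=0`` recovers the background-free model).

    Raises ``ValueError`` for fewer than 50 displacements or an unsupported
    component count.
    """
    if n_components not in (1, 2, 3):
        raise ValueError("n_components must be 1, 2 or 3")
    if len(ds) < MIN_FIT_DISPLACEMENTS:
        raise ValueError(
            f"refusing to fit {len(ds)} displacements "
            f"(need >= {MIN_FIT_DISPLACEMENTS}); collect more data or pool cells"
        )
    return _fit_mixture(ds.r, ds.dt_ms, ds.r_max_nm, n_components, fix_b)


def closed_form_diffusion(ds: DisplacementSet) -> float:
    """Background-free, untruncated moment estimator D = <r^2> / (4 dt).

    For the pure 2D random walk the mean squared displacement over the fixed
    interval is 4 D dt, so this is both the method-of-moments estimate and
    the exact MLE of the untruncated Rayleigh model. Returns um^2/s.
    """
    if len(ds) == 0:
        raise ValueError("empty displacement set")
    return _moment_D(ds.r, ds.dt_ms)


# ---------------------------------------------------------------------------
# diffusivity maps
# ---------------------------------------------------------------------------

def build_diffusion_map(
    ds: DisplacementSet,
    pixel_nm: float = 50.0,
    min_count: int = 20,
    b: float = 0.0,
) -> DiffusionMap:
    """Reconstruct a local-diffusivity map on a square grid.

    Displacements are binned by their *starting* position into
    ``pixel_nm``-sized pixels covering the bounding box of the set (intended
    to be one aligned cell). Each pixel with at least ``min_count``
    displacements gets a single-component truncated-model MLE fit of its own;
    the background slope ``b`` is shared across pixels (fit it once per cell
    or region and pass it in — a per-pixel b is not identifiable at 50 nm).
    Pixels below ``min_count`` are masked (NaN).
    """
    if len(ds) == 0:
        return DiffusionMap(np.full((0, 0), np.nan), np.zeros((0, 0), int),
                            (0.0, 0.0), pixel_nm, min_count)
    x0, y0 = ds.x0, ds.y0
    ox = np.floor(x0.min() / pixel_nm) * pixel_nm
    oy = np.floor(y0.min() / pixel_nm) * pixel_nm
    ix = ((x0 - ox) // pixel_nm).astype(int)
    iy = ((y0 - oy) // pixel_nm).astype(int)
    nx, ny = ix.max() + 1, iy.max() + 1

    counts = np.zeros((ny, nx), int)
    np.add.at(counts, (iy, ix), 1)
    D = np.full((ny, nx), np.nan)

    flat = iy * nx + ix
    order = np.argsort(flat, kind="stable")
    flat_sorted = flat[order]
    r_sorted = ds.r[order]
    uniq, starts = np.unique(flat_sorted, return_index=True)
    ends = list(starts[1:]) + [flat_sorted.size]
    for u, s, e in zip(uniq, starts, ends):
        if e - s < min_count:
            continue
        fit = _fit_mixture(r_sorted[s:e], ds.dt_ms, ds.r_max_nm, 1, fix_b=b)
        D[u // nx, u % nx] = fit.components[0][0]
    return DiffusionMap(D, counts, (float(ox), float(oy)), pixel_nm, min_count)
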