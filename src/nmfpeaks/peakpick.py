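"""Turn factorized 1D component shapes into a calibrated peak list.

Each factorized component contributes one non-negative 1D profile per
spectral axis (a basis column, a source row, and — for 3D data — the
per-slice weight profile along the slab axis).  For every profile the peak
position is found by sliding an ideal Gaussian of average linewidth across
the profile and maximizing the normalized scalar product (cosine), the
linewidth is then adapted by a bounded 1D least-squares fit, and the final
sub-grid position and apex height come from a three-point parabolic
interpolation of the profile around the matched centre.  A user-defined
intensity threshold (fraction of the strongest peak) prunes weak
components.

When peak positions along some axes are known a priori (from a consistently
referenced companion experiment), the basis matrix is built from Gaussians
at the known positions and held fixed while only the source matrix is
updated — the original ISRA setting — so only the unknown coordinates are
estimated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar, nnls

from . import nmf
from .nmf import FactorPair, factorize, preprocess
from .ntf2 import Ntf2Factorization, component_slab_profile
from .spectra_io import AxisCalibration, Peak, PeakList, Spectrum

__all__ = [
    "ComponentShape",
    "GaussianModel",
    "Peak",
    "PeakList",
    "ReferencingError",
    "match_gaussian",
    "adapt_linewidth",
    "parabolic_interpolate",
    "assemble_peaks",
    "pick_with_known_positions",
    "FWHM_PER_SIGMA",
]

logger = logging.getLogger(__name__)

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548

DEFAULT_AVG_WIDTH = 2.0  # Gaussian sd, grid points
DEFAULT_WIDTH_BOUNDS = (0.5, 10.0)
DEFAULT_THRESHOLD = 0.02


class ReferencingError(ValueError):
    """A priori peak position inconsistent with the spectrum calibration."""


@dataclass
class ComponentShape:
    """One 1D non-negative profile attributed to a spectral axis."""

    values: np.ndarray
    axis: AxisCalibration | None = None
    component_id: int = -1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.axis is not None and self.values.size != self.axis.n_points:
            raise ValueError(
                f"shape has {self.values.size} points, axis {self.axis.n_points}"
            )


@dataclass
class GaussianModel:
    """An ideal Gaussian line: centre (points), width (sd, points), amplitude
    (projection coefficient onto the unit-l2 Gaussian)."""

    center: float
    width: float
    amplitude: float
    at_bound: bool = False


def _unit_gaussian(n: int, center: float, width: float) -> np.ndarray:
    g = np.exp(-((np.arange(n) - center) ** 2) / (2.0 * width * width))
    nrm = np.linalg.norm(g)
    return g / nrm if nrm > 0 else g


def match_gaussian(shape, avg_width: float = DEFAULT_AVG_WIDTH) -> GaussianModel | None:
    """Best integer centre of an ideal Gaussian of the average linewidth.

    Slides a unit-l2 Gaussian of sd ``avg_width`` over every grid point and
    keeps the centre maximizing the normalized scalar product with the
    profile (ties broken toward the lower index).  Returns ``None`` for an
    all-zero profile (no peak), which callers treat as a sentinel.
    """
    v = shape.values if isinstance(shape, ComponentShape) else np.asarray(shape, float)
    if v.ndim != 1:
        raise ValueError("match_gaussian expects a 1D profile")
    if not np.any(v > 0):
        return None
    n = v.size
    scores = np.empty(n)
    for c in range(n):
        scores[c] = _unit_gaussian(n, c, avg_width) @ v
    c = int(np.argmax(scores))
    return GaussianModel(center=float(c), width=float(avg_width),
                         amplitude=float(scores[c]))


def adapt_linewidth(
    shape,
    model: GaussianModel,
    width_bounds: tuple[float, float] = DEFAULT_WIDTH_BOUNDS,
) -> GaussianModel:
    """Refine the Gaussian width at fixed centre by bounded least squares.

    For a unit-l2 Gaussian g(w), minimizing ||v - a g(w)||^2 over the
    amplitude a gives a = <g(w), v>, so the optimal width maximizes the
    scalar product; a bounded scalar minimization handles it.  A width that
    lands on a bound is returned clamped with ``at_bound`` set.
    """
    v = shape.values if isinstance(shape, ComponentShape) else np.asarray(shape, float)
    lo, hi = width_bounds
    try:
        res = minimize_scalar(
            lambda w: -(_unit_gaussian(v.size, model.center, w) @ v),
            bounds=(lo, hi),
            method="bounded",
        )
        w = float(res.x)
    except Exception:  # optimizer failure: keep the average width
        logger.warning("linewidth fit failed for centre %.1f; keeping avg width",
                       model.center)
        w = model.width
    at_bound = bool(min(w - lo, hi - w) < 1e-3)
    if at_bound:
        w = lo if (w - lo) < (hi - w) else hi
    amp = float(_unit_gaussian(v.size, model.center, w) @ v)
    return GaussianModel(center=model.center, width=w, amplitude=amp,
                         at_bound=at_bound)


def parabolic_interpolate(
    y_minus: float, y0: float, y_plus: float
) -> tuple[float, float]:
    """Sub-grid apex of the parabola through three points around a maximum.

    Returns ``(offset, height)`` with the offset in (-0.5, 0.5] relative to
    the centre sample.  A flat triple degenerates to offset 0, height y0.
    """
    if y0 < y_minus or y0 < y_plus:
        raise ValueError(
            f"({y_minus}, {y0}, {y_plus}) is not a local maximum triple"
        )
    denom = y_minus - 2.0 * y0 + y_plus
    if denom == 0.0:
        return 0.0, float(y0)
    offset = (y_minus - y_plus) / (2.0 * denom)
    height = y0 - 0.25 * (y_minus - y_plus) * offset
    return float(offset), float(height)


def _interp_apex(values: np.ndarray, center: int) -> tuple[float, float]:
    """Parabolic apex of a 1D profile around an integer centre (clamped to
    the grid interior so a 3-point stencil always exists)."""
    n = values.size
    c = int(np.clip(center, 1, n - 2))
    ym, y0, yp = float(values[c - 1]), float(values[c]), float(values[c + 1])
    if y0 < ym or y0 < yp:  # matched centre off the local apex; snap to it
        c2 = c - 1 if ym >= yp else c + 1
        c2 = int(np.clip(c2, 1, n - 2))
        ym, y0, yp = float(values[c2 - 1]), float(values[c2]), float(values[c2 + 1])
        if y0 >= ym and y0 >= yp:
            c = c2
        else:
            return float(c), float(values[c])
    off, height = parabolic_interpolate(ym, y0, yp)
    return c + off, height


def _measure_axis_shape(
    values: np.ndarray,
    avg_width: float,
    width_bounds: tuple[float, float],
    baseline: str = "median",
) -> tuple[float, float, float] | None:
    """(fractional position, baseline-corrected apex height, fwhm points).

    The zero-clipping of noise gives factorized shapes a positive offset;
    the profile median estimates it (a clean localized line has median ~0).
    """
    model = match_gaussian(values, avg_width)
    if model is None:
        return None
    model = adapt_linewidth(ComponentShape(values), model, width_bounds)
    pos, apex = _interp_apex(values, int(model.center))
    if baseline == "median":
        apex = max(apex - float(np.median(values)), 0.0)
    return pos, apex, model.width * FWHM_PER_SIGMA


def _gaussian_model_nd(shape, pos, sigmas) -> np.ndarray:
    """Unit-apex separable Gaussian on an N-dimensional grid."""
    out = None
    for n, c, s in zip(shape, pos, sigmas):
        g = np.exp(-((np.arange(n) - c) ** 2) / (2.0 * s * s))
        out = g if out is None else np.multiply.outer(out, g)
    return out


def _refine_records(records, observed, axis_width_bounds, passes,
                    share_widths=False):
    """Model-based polish of picked peaks by joint lineshape fitting.

    The factorization's 1D shapes can remain slightly mixed between
    strongly overlapping components even at small residual (the cost
    surface is nearly flat along mixing directions), and under noise they
    carry a share of the noise floor, which biases apex products.  The
    polish therefore fits the classic explicit peak model to the spectrum
    itself: all component amplitudes, centres and per-axis widths plus a
    constant background level (absorbing the positive pedestal that
    zero-clipped noise leaves) are adjusted simultaneously by bounded
    least squares, initialized at the shape-derived estimates.  Centres
    may move at most 3 points from the factorization's answer — the
    factorization localizes, the fit only polishes.

    ``axis_width_bounds`` gives per-axis (lo, hi) sigma bounds; a band
    around the average linewidth keeps noise-broadened components from
    degenerating into background blobs.  If the joint fit fails, a plain
    non-negative least-squares re-fit of the amplitudes alone is used.

    ``records`` entries are ``[component_id, pos list, intensity,
    sigma list]`` and are updated in place; ``passes`` caps the number of
    optimizer restarts from the updated parameters.
    """
    from scipy.optimize import least_squares

    shape = observed.shape
    ndim = len(shape)
    J = len(records)
    Yobs = np.maximum(observed, 0.0)
    # fit only where the model has support: union of +-6 sigma boxes
    mask = np.zeros(shape, dtype=bool)
    for rec in records:
        box = tuple(
            slice(max(int(c - 6 * s), 0), min(int(c + 6 * s) + 1, n))
            for c, s, n in zip(rec[1], rec[3], shape)
        )
        mask[box] = True
    idx = np.nonzero(mask)
    coords = [ix.astype(float) for ix in idx]
    yfit = Yobs[idx]

    def unpack(theta):
        amps = theta[:J]
        centers = np.asarray(theta[J:J + J * ndim]).reshape(J, ndim)
        if share_widths:  # one linewidth per axis for the whole cluster
            sigmas = np.tile(np.asarray(theta[J + J * ndim:-1]), (J, 1))
        else:
            sigmas = np.asarray(theta[J + J * ndim:-1]).reshape(J, ndim)
        return amps, centers, sigmas, theta[-1]

    def residual(theta):
        amps, centers, sigmas, bg = unpack(theta)
        out = np.full(yfit.size, bg)
        for j in range(J):
            term = np.full(yfit.size, amps[j])
            for a in range(ndim):
                term = term * np.exp(
                    -((coords[a] - centers[j, a]) ** 2)
                    / (2.0 * sigmas[j, a] ** 2)
                )
            out += term
        return out - yfit

    if share_widths:
        sig0 = [float(np.median([rec[3][a] for rec in records]))
                for a in range(ndim)]
        sig_lo = [axis_width_bounds[a][0] for a in range(ndim)]
        sig_hi = [axis_width_bounds[a][1] for a in range(ndim)]
    else:
        sig0 = [s for rec in records for s in rec[3]]
        sig_lo = [axis_width_bounds[a][0] for _ in records for a in range(ndim)]
        sig_hi = [axis_width_bounds[a][1] for _ in records for a in range(ndim)]
    p0 = ([max(rec[2], 1e-9) for rec in records]
          + [c for rec in records for c in rec[1]]
          + sig0 + [0.0])
    lower = ([0.0] * J
             + [c - 3.0 for rec in records for c in rec[1]]
             + sig_lo + [0.0])
    upper = ([np.inf] * J
             + [c + 3.0 for rec in records for c in rec[1]]
             + sig_hi + [np.inf])
    p0 = np.clip(p0, lower, upper)
    try:
        res = least_squares(residual, p0, bounds=(lower, upper),
                            method="trf", max_nfev=100 * max(1, passes))
        amps, centers, sigmas, _bg = unpack(res.x)
        for k, rec in enumerate(records):
            rec[2] = float(amps[k])
            rec[1] = [float(np.clip(centers[k, a], 0, shape[a] - 1))
                      for a in range(ndim)]
            rec[3] = [float(sigmas[k, a]) for a in range(ndim)]
    except Exception:
        logger.warning("joint lineshape fit failed; re-fitting amplitudes only")
        M = np.stack(
            [_gaussian_model_nd(shape, rec[1], rec[3])[idx] for rec in records],
            axis=1,
        )
        amps, _ = nnls(np.column_stack([M, np.ones(yfit.size)]), yfit)
        for k, rec in enumerate(records):
            rec[2] = float(amps[k])
    return records


def _component_axis_shapes(F, S: Spectrum) -> list[list[np.ndarray]]:
    """Per component, one 1D profile per spectrum axis (in S's axis order).

    2D FactorPair: basis column for axis 0, source row for axis 1.
    3D Ntf2Factorization: basis column for the first non-slab axis, the
    source row taken at the slice of maximal component weight (row-
    normalized, rescaled by the interpolated slab profile when measured)
    for the second, and the slab profile itself for the slab axis.
    """
    shapes: list[list[np.ndarray]] = []
    if isinstance(F, FactorPair):
        if S.ndim != 2:
            raise ValueError("FactorPair pairs with a 2D spectrum")
        for j in range(F.rank):
            shapes.append([F.A[:, j].copy(), F.X[j, :].copy()])
        return shapes
    if isinstance(F, Ntf2Factorization):
        if S.ndim != 3:
            raise ValueError("Ntf2Factorization pairs with a 3D spectrum")
        non_slab = [a for a in range(3) if a != F.slab_axis]
        for j in range(F.n_components):
            prof = component_slab_profile(F, j)
            q_star = int(np.argmax(prof))
            d = prof[q_star]
            xrow = F.Xq[q_star][j, :].copy()
            if d > 0:
                xrow = xrow / d  # unit-l1 source shape at the best slice
            per_axis: list[np.ndarray | None] = [None, None, None]
            per_axis[non_slab[0]] = F.A[:, j].copy()
            per_axis[non_slab[1]] = xrow
            per_axis[F.slab_axis] = prof
            shapes.append(per_axis)  # type: ignore[arg-type]
        return shapes
    raise TypeError(f"unsupported factorization type {type(F).__name__}")


def assemble_peaks(
    F,
    S: Spectrum,
    threshold: float = DEFAULT_THRESHOLD,
    avg_widths=None,
    width_bounds: tuple[float, float] = DEFAULT_WIDTH_BOUNDS,
    baseline: str = "median",
    refine_passes: int = 3,
    share_widths: bool = False,
) -> PeakList:
    """Build the final peak list from a factorization.

    Every component's per-axis 1D shapes are Gaussian-matched, width-adapted
    and parabolically interpolated; the peak intensity is the scale-restored
    product of the per-axis apex heights (for 3D, the source shape is unit-
    l1-normalized and the slab-profile apex carries the slice weight, so the
    product is the reconstruction amplitude at the apex).  When
    ``refine_passes`` > 0 the shape-based estimates are then polished
    against the model reconstruction (see ``_refine_records``), which
    deconvolutes the residual component mixing that survives between
    strongly overlapping peaks.  Components whose intensity falls below
    ``threshold`` times the strongest are dropped, as are components with
    no positive profile on some axis.
    """
    ndim = S.ndim
    if avg_widths is None:
        avg_widths = (DEFAULT_AVG_WIDTH,) * ndim
    elif np.isscalar(avg_widths):
        avg_widths = (float(avg_widths),) * ndim
    records = []
    for j, per_axis in enumerate(_component_axis_shapes(F, S)):
        meas = []
        for a in range(ndim):
            m = _measure_axis_shape(per_axis[a], avg_widths[a], width_bounds, baseline)
            if m is None:
                logger.info("component %d dropped: no positive shape on axis %d", j, a)
                meas = None
                break
            meas.append(m)
        if meas is None:
            continue
        intensity = F.scale * float(np.prod([h for _, h, _ in meas]))
        records.append([j, [m[0] for m in meas], intensity,
                        [m[2] / FWHM_PER_SIGMA for m in meas]])
    if not records:
        return PeakList(peaks=[], source="assemble_peaks",
                        axis_labels=tuple(ax.label for ax in S.axes))
    if refine_passes > 0:
        # restrict the refit to a physically plausible band around the
        # average linewidth so noise-broadened shapes cannot degenerate
        refine_bounds = [
            (max(width_bounds[0], avg_widths[a] / 2.0),
             min(width_bounds[1], avg_widths[a] * 2.0))
            for a in range(ndim)
        ]
        records = _refine_records(records, S.data, refine_bounds,
                                  refine_passes, share_widths=share_widths)
    imax = max(r[2] for r in records)
    peaks = []
    for j, pos, intensity, sigmas in records:
        if intensity < threshold * imax or intensity <= 0:
            continue
        ppm = tuple(
            S.axes[a].point_to_ppm(float(np.clip(pos[a], 0, S.axes[a].n_points - 1)))
            for a in range(ndim)
        )
        peaks.append(Peak(
            positions_points=tuple(pos),
            positions_ppm=ppm,
            intensity=intensity,
            linewidths=tuple(s * FWHM_PER_SIGMA for s in sigmas),
            component_id=j,
        ))
    peaks.sort(key=lambda p: -p.intensity)
    return PeakList(peaks=peaks, source="assemble_peaks",
                    axis_labels=tuple(ax.label for ax in S.axes))


# --------------------------------------------------------------------------
# constrained picking with a priori known positions
# --------------------------------------------------------------------------

def _fixed_basis_fit(
    Y: np.ndarray,
    A: np.ndarray,
    *,
    max_iter: int = 5000,
    eps: float = 1e-12,
    plateau_window: int = 10,
    plateau_tol: float = 1e-8,
    seed: int | None = None,
) -> np.ndarray:
    """ISRA proper: update only X under a fixed, known basis matrix."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.1, 1.1, size=(A.shape[1], Y.shape[1]))
    AtY = A.T @ Y
    AtA = A.T @ A
    prev = np.inf
    stagnant = 0
    for _ in range(max_iter):
        X = X * AtY / (AtA @ X + eps)
        R = Y - A @ X
        d = float(np.vdot(R, R).real)
        stagnant = stagnant + 1 if (prev - d) / max(d, 1e-300) < plateau_tol else 0
        prev = d
        if stagnant >= plateau_window:
            break
    return X


def pick_with_known_positions(
    S: Spectrum,
    known: PeakList,
    known_axes=(0,),
    *,
    avg_widths=None,
    width_bounds: tuple[float, float] = DEFAULT_WIDTH_BOUNDS,
    threshold: float = DEFAULT_THRESHOLD,
    position_tolerance: float = 0.5,
    seed: int | None = None,
    r: int | None = None,
    **config,
) -> PeakList:
    """Pick peaks when positions along some axes are already known.

    The basis matrix is built from Gaussians of the average linewidth
    centred at the known positions on the constrained axes (their outer
    product, row-unfolded, when two axes are constrained), held fixed while
    the source matrix is fitted by the X-only multiplicative rule.  Output
    peaks carry the known coordinates verbatim on constrained axes and the
    newly determined coordinates elsewhere.

    Known positions are taken from ``positions_ppm`` unless they are NaN, in
    which case ``positions_points`` is used directly.  A known position
    farther than ``position_tolerance`` points outside the grid raises
    :class:`ReferencingError` naming the axis.
    """
    ndim = S.ndim
    known_axes = tuple(sorted(int(a) % ndim for a in known_axes))
    free_axes = [a for a in range(ndim) if a not in known_axes]
    if not known.peaks:
        warnings.warn("empty known-peak list: falling back to unconstrained "
                      "factorization", stacklevel=2)
        if ndim != 2:
            raise ValueError("unconstrained fallback supports 2D spectra; "
                             "use ntf2.factorize_ntf2 for 3D data")
        Yn, scale = preprocess(S.data)
        rr = r if r is not None else nmf.select_components(Yn, seed=seed).chosen_r
        pair, _ = factorize(Yn, rr, seed=seed, scale=scale, **config)
        return assemble_peaks(pair, S, threshold=threshold, avg_widths=avg_widths,
                              width_bounds=width_bounds)
    if len(free_axes) != 1:
        raise ValueError(
            f"{len(known_axes)} constrained axes leave {len(free_axes)} free; "
            "exactly one axis must remain unconstrained"
        )
    if avg_widths is None:
        avg_widths = (DEFAULT_AVG_WIDTH,) * ndim
    elif np.isscalar(avg_widths):
        avg_widths = (float(avg_widths),) * ndim

    # known positions in grid points, per constrained axis
    known_points: list[list[float]] = []
    for p_idx, pk in enumerate(known.peaks):
        pts = []
        for a in known_axes:
            ax = S.axes[a]
            ppm = pk.positions_ppm[a] if len(pk.positions_ppm) > a else float("nan")
            if np.isfinite(ppm):
                pt = ax.ppm_to_point(ppm)
            else:
                pt = pk.positions_points[a]
            if not -position_tolerance <= pt <= ax.n_points - 1 + position_tolerance:
                raise ReferencingError(
                    f"known peak {p_idx}: position {pt:.2f} points off axis {a} "
                    f"({ax.label or 'unlabelled'}, 0..{ax.n_points - 1})"
                )
            pts.append(float(np.clip(pt, 0, ax.n_points - 1)))
        known_points.append(pts)

    # orient data: constrained axes first (rows, unfolded), free axis last
    data = np.transpose(S.data, known_axes + tuple(free_axes))
    row_shape = data.shape[:len(known_axes)]
    Y = data.reshape(int(np.prod(row_shape)), data.shape[-1])
    Yn, scale = preprocess(Y)

    cols = []
    for pts in known_points:
        g = np.ones(1)
        for a, pt in zip(known_axes, pts):
            ga = np.exp(-((np.arange(S.axes[a].n_points) - pt) ** 2)
                        / (2.0 * avg_widths[a] ** 2))
            g = np.kron(g, ga)
        s = g.sum()
        cols.append(g / s if s > 0 else g)
    A = np.column_stack(cols)

    X = _fixed_basis_fit(Yn, A, seed=seed, **config)
    free_ax = S.axes[free_axes[0]]
    peaks = []
    records = []
    for j, pk in enumerate(known.peaks):
        m = _measure_axis_shape(X[j], avg_widths[free_axes[0]], width_bounds)
        if m is None:
            logger.info("known peak %d: no signal on the free axis; dropped", j)
            continue
        pos_free, h_free, fwhm_free = m
        hA = float(A[:, j].max())  # apex of the known-axis basis column
        records.append((j, pk, pos_free, h_free, fwhm_free,
                        scale * hA * h_free))
    if not records:
        return PeakList(peaks=[], source="pick_with_known_positions",
                        axis_labels=tuple(ax.label for ax in S.axes))
    imax = max(rec[5] for rec in records)
    for j, pk, pos_free, h_free, fwhm_free, intensity in records:
        if intensity < threshold * imax:
            continue
        pos_pts, ppm, widths = [], [], []
        for a in range(ndim):
            if a in known_axes:
                i_known = known_axes.index(a)
                pt = known_points[j][i_known]
                pos_pts.append(pt)
                given = pk.positions_ppm[a] if len(pk.positions_ppm) > a else float("nan")
                ppm.append(given if np.isfinite(given) else S.axes[a].point_to_ppm(pt))
                widths.append(avg_widths[a] * FWHM_PER_SIGMA)
            else:
                pos_pts.append(pos_free)
                ppm.append(free_ax.point_to_ppm(
                    float(np.clip(pos_free, 0, free_ax.n_points - 1))))
                widths.append(fwhm_free)
        peaks.append(Peak(
            positions_points=tuple(pos_pts),
            positions_ppm=tuple(ppm),
            intensity=intensity,
            linewidths=tuple(widths),
            component_id=j,
            assignment=pk.assignment,
        ))
    peaks.sort(key=lambda p: -p.intensity)
    return PeakList(peaks=peaks, source="pick_with_known_positions",
                    axis_labels=tuple(ax.label for ax in S.axes))
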