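"""Thin-film interference (TFI) reflectivity model and thickness fitting.

A lamella of vitreous ice behaves as a thin film: light reflected from its
two surfaces interferes, so the reflected intensity oscillates with the
film thickness d:

    r(d, λ, T) = r_mea + r_A · env(d) · cos(4π·d·n2(λ,T)/λ + π)

where r_mea is the mean reflectivity, r_A the oscillation amplitude, n2
the refractive index of amorphous ice at wavelength λ and temperature T,
and env(d) a decaying envelope with scale L (default 500 nm) accounting
for scattering and coherence loss.  The printed form of the envelope is
typographically ambiguous; both the exponential exp(−d/L) (default,
coherence-loss reading) and the Gaussian exp(−(d/L)²) are provided.
Successive extrema are spaced by half an optical wavelength in the film,
P = λ/(2·n2) ≈ 181 nm at λ = 463 nm.

Fitting uses a *normalized* model: per-pixel min-max normalization over
the observed milling series maps intensities to [0, 1] and the model is
normalized the same way over the thickness interval the series covered,
which makes the fit invariant to affine intensity transforms.  Branch
confinement (search within ± half a period of the geometric initial
estimate) resolves the interference-order ambiguity.

The packaged n2(λ, T) dispersion is a synthetic stand-in: a Cauchy model
n = A(T) + B/λ² with a weak linear temperature coefficient, anchored to
the one measured value used throughout (n2 = 1.28 at 109 K, mid-visible).
It is bilinear-interpolated exactly like a tabulated dataset would be.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import AmbiguousOffsetError
from .io import ThicknessMap

# --------------------------------------------------------------------------
# refractive index of amorphous ice (synthetic dispersion table, see module
# docstring): n = A(T) + B / lambda^2, anchored at n2(550 nm, 109 K) = 1.28
_CAUCHY_B_NM2 = 3100.0
_DN_DT_PER_K = -2.0e-5
_TABLE_WAVELENGTHS_NM = np.arange(400.0, 701.0, 25.0)
_TABLE_TEMPERATURES_K = np.arange(100.0, 141.0, 10.0)


def _dispersion_table() -> np.ndarray:
    a = 1.28 - _CAUCHY_B_NM2 / 550.0**2 + _DN_DT_PER_K * (_TABLE_TEMPERATURES_K - 109.0)
    return a[None, :] + _CAUCHY_B_NM2 / _TABLE_WAVELENGTHS_NM[:, None] ** 2


_N2_INTERP = RegularGridInterpolator(
    (_TABLE_WAVELENGTHS_NM, _TABLE_TEMPERATURES_K),
    _dispersion_table(),
    method="linear",
    bounds_error=False,
    fill_value=None,  # linear extrapolation outside the grid
)


def refractive_index_ice(wavelength_nm: float, temperature_K: float = 109.0) -> float:
    """n2 of amorphous ice by bilinear interpolation of the packaged table.

    Valid over ≈400–700 nm and ≈100–140 K; queries outside that range are
    linearly extrapolated with a warning.
    """
    lam_ok = _TABLE_WAVELENGTHS_NM[0] <= wavelength_nm <= _TABLE_WAVELENGTHS_NM[-1]
    t_ok = _TABLE_TEMPERATURES_K[0] <= temperature_K <= _TABLE_TEMPERATURES_K[-1]
    if not (lam_ok and t_ok):
        warnings.warn(
            f"({wavelength_nm} nm, {temperature_K} K) outside the dispersion "
            "table; extrapolating",
            stacklevel=2,
        )
    return float(_N2_INTERP((wavelength_nm, temperature_K)))


# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TfiParams:
    """Reflectivity-model parameters.

    ``n2`` defaults to the packaged dispersion at (wavelength, temperature).
    ``envelope`` is ``"exponential"`` (default) or ``"gaussian"``.
    """

    wavelength_nm: float = 463.0
    r_mea: float = 1.0
    r_A: float = 0.5
    L_nm: float = 500.0
    temperature_K: float = 109.0
    n2: float = field(default=None)  # type: ignore[assignment]
    envelope: str = "exponential"

    def __post_init__(self) -> None:
        if self.L_nm <= 0:
            raise ValueError("L_nm must be positive")
        if self.r_A < 0:
            raise ValueError("r_A must be >= 0")
        if self.envelope not in ("exponential", "gaussian"):
            raise ValueError(f"unknown envelope {self.envelope!r}")
        if self.n2 is None:
            object.__setattr__(
                self,
                "n2",
                refractive_index_ice(self.wavelength_nm, self.temperature_K),
            )
        if self.n2 <= 1:
            raise ValueError("n2 must exceed 1")

    @property
    def period_nm(self) -> float:
        """Extrema spacing λ/(2·n2) of the interference oscillation."""
        return self.wavelength_nm / (2.0 * self.n2)


def reflectivity(d_nm, params: TfiParams):
    """Model reflectivity r(d) for thickness d (nm); r(0) = r_mea − r_A."""
    d = np.asarray(d_nm, dtype=float)
    if np.any(d < 0):
        raise ValueError("thickness must be >= 0")
    x = d / params.L_nm
    env = np.exp(-(x**2)) if params.envelope == "gaussian" else np.exp(-x)
    r = params.r_mea + params.r_A * env * np.cos(
        4.0 * np.pi * d * params.n2 / params.wavelength_nm + np.pi
    )
    return r if r.ndim else float(r)


@dataclass(frozen=True)
class FitResult:
    d_nm: float
    residual: float
    branch_index: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.d_nm < 0 or self.branch_index < 0:
            raise ValueError("d_nm and branch_index must be >= 0")


def _minmax_normalize(x: np.ndarray):
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo <= 0:
        raise AmbiguousOffsetError("intensity has no dynamic range")
    return (x - lo) / (hi - lo)


@dataclass(frozen=True)
class TraceFit:
    offset_nm: float
    d_nm: np.ndarray
    residual: float


def fit_trace(
    intensity_t: np.ndarray,
    timestamps_s: np.ndarray,
    mill_rate_nm_s: float,
    params: TfiParams,
    d_offset_search_nm=(0.0, 2000.0),
    grid_step_nm: float = 1.0,
) -> TraceFit:
    """Fit the thickness offset of a constant-rate thinning trace.

    During even thinning the thickness at time t is
    ``d(t) = offset + rate·(t_end − t)``: the timestamps fix the thickness
    *decrements* and only the final-thickness offset is unknown.  The
    offset minimizing the squared error between the min-max-normalized
    intensity trace and the equally normalized reflectivity model is found
    by a grid scan with parabolic refinement.

    Raises :class:`AmbiguousOffsetError` when the trace covers less than
    one interference period (several offsets would fit equally well) or
    carries no intensity modulation at all.
    """
    intensity_t = np.asarray(intensity_t, dtype=float)
    timestamps_s = np.asarray(timestamps_s, dtype=float)
    if intensity_t.shape != timestamps_s.shape:
        raise ValueError("intensity and timestamps must have equal length")
    span_nm = mill_rate_nm_s * (timestamps_s[-1] - timestamps_s[0])
    if span_nm < params.period_nm:
        raise AmbiguousOffsetError(
            f"trace spans {span_nm:.0f} nm < one period ({params.period_nm:.0f} nm)"
        )
    data = _minmax_normalize(intensity_t)
    decrement = mill_rate_nm_s * (timestamps_s[-1] - timestamps_s)

    offsets = np.arange(d_offset_search_nm[0], d_offset_search_nm[1], grid_step_nm)
    sse = np.empty(offsets.size)
    for k, off in enumerate(offsets):
        model = reflectivity(off + decrement, params)
        m = model - model.min()
        peak = m.max()
        m = m / peak if peak > 0 else m
        sse[k] = float(np.sum((data - m) ** 2))
    k = int(np.argmin(sse))
    best = offsets[k]
    if 0 < k < offsets.size - 1:  # parabolic sub-grid refinement
        y0, y1, y2 = sse[k - 1], sse[k], sse[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom > 0:
            best = best + 0.5 * grid_step_nm * (y0 - y2) / denom
    return TraceFit(offset_nm=float(best), d_nm=best + decrement, residual=float(sse[k]))


def _normalized_model(params: TfiParams, d_lo: float, d_hi: float):
    """min/max of r over [d_lo, d_hi] for model normalization."""
    dd = np.arange(max(d_lo, 0.0), d_hi, 1.0)
    r = reflectivity(dd, params)
    return float(r.min()), float(r.max())


#: above this thickness TFI fringes wash out and fitting is not attempted
MAX_FIT_THICKNESS_NM = 1500.0


def fit_thickness_map(
    frame: np.ndarray,
    init_map: ThicknessMap,
    params: TfiParams,
    norm_min: np.ndarray,
    norm_max: np.ndarray,
    mask: np.ndarray | None = None,
    norm_span_nm: float | None = None,
    max_fit_thickness_nm: float = MAX_FIT_THICKNESS_NM,
    grid_step_nm: float = 1.0,
    tie_break_weight: float = 1e-4,
) -> ThicknessMap:
    """Per-pixel error minimization refining a geometric thickness map.

    For each masked pixel the intensity is normalized with the per-pixel
    series minimum/maximum (``norm_min``/``norm_max``) and compared with
    the model normalized over the thickness interval the series covered
    (``norm_span_nm`` above the current estimate, default two periods).
    The search is confined to init ± P/2 with P = λ/(2·n2): the geometric
    initialization selects the interference branch.  Ties between the two
    monotone flanks of a fringe are broken toward the initial estimate via
    a small quadratic penalty.  Pixels with no initial estimate, an
    invalid normalization or an initial estimate above the fringe-contrast
    limit (~1.5 μm) are flagged invalid, not fitted.

    Returns a new :class:`ThicknessMap` whose metadata carries the
    per-pixel residual (``"residual"``) and the uniformity sigma over the
    fitted region (``"uniformity_sigma_nm"``).
    """
    frame = np.asarray(frame, dtype=float)
    init = init_map.values_nm
    if frame.shape != init.shape:
        raise ValueError("frame and init_map shapes differ")
    if mask is None:
        mask = init_map.mask.copy()
    else:
        mask = np.asarray(mask, dtype=bool) & init_map.mask
    period = params.period_nm
    span = norm_span_nm if norm_span_nm is not None else 2.0 * period

    out = np.full(frame.shape, np.nan)
    resid = np.full(frame.shape, np.nan)
    fitted = np.zeros(frame.shape, dtype=bool)
    half = 0.5 * period
    offsets = np.arange(-half, half, grid_step_nm)

    for i, j in zip(*np.nonzero(mask)):
        d0 = init[i, j]
        rng_ok = norm_max[i, j] - norm_min[i, j] > 0
        if not np.isfinite(d0) or not rng_ok or d0 > max_fit_thickness_nm:
            continue
        data = (frame[i, j] - norm_min[i, j]) / (norm_max[i, j] - norm_min[i, j])
        # normalize the model over the same thickness interval the series
        # min/max were observed on: [current estimate, estimate + span]
        lo, hi = _normalized_model(params, d0, d0 + span)
        ds = d0 + offsets
        ds = ds[ds >= 0]
        m = (reflectivity(ds, params) - lo) / (hi - lo)
        obj = (data - m) ** 2 + tie_break_weight * ((ds - d0) / period) ** 2
        k = int(np.argmin(obj))
        best = ds[k]
        if 0 < k < ds.size - 1:
            y0, y1, y2 = obj[k - 1], obj[k], obj[k + 1]
            denom = y0 - 2 * y1 + y2
            if denom > 0:
                best = best + 0.5 * grid_step_nm * (y0 - y2) / denom
        out[i, j] = max(best, 0.0)
        resid[i, j] = float(obj[k])
        fitted[i, j] = True

    sigma = float(np.std(out[fitted])) if fitted.any() else np.nan
    meta = dict(init_map.metadata)
    meta.update(
        {
            "method_params": {
                "wavelength_nm": params.wavelength_nm,
                "n2": params.n2,
                "L_nm": params.L_nm,
                "envelope": params.envelope,
            },
            "uniformity_sigma_nm": sigma,
        }
    )
    tm = ThicknessMap(
        out, init_map.pixel_size_um, method="tfi", mask=fitted, metadata=meta
    )
    tm.metadata["residual"] = resid
    return tm


def uniformity_sigma(tmap: ThicknessMap, roi: np.ndarray | tuple | None = None) -> float:
    """One-standard-deviation thickness uniformity over a region of interest.

    ``roi`` may be a boolean mask or a (slice, slice) tuple; ``None`` uses
    the full valid mask.  Population SD, in nm.
    """
    sel = np.zeros(tmap.values_nm.shape, dtype=bool)
    if roi is None:
        sel[:] = True
    elif isinstance(roi, tuple):
        sel[roi] = True
    else:
        sel = np.asarray(roi, dtype=bool)
    sel &= tmap.mask & np.isfinite(tmap.values_nm)
    if not sel.any():
        raise ValueError("empty ROI")
    return float(np.std(tmap.values_nm[sel]))


def with_wavelength(params: TfiParams, wavelength_nm: float) -> TfiParams:
    """Same model constants at another wavelength (n2 re-derived)."""
    return replace(params, wavelength_nm=wavelength_nm, n2=None)
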