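"""Geometric lamella thickness from reflected-light microscopy (RLM).

FIB milling at a shallow angle θ (typically 10°) leaves wedge-shaped ends
on the lamella.  Viewed from the foil side in reflected light, the wedge
appears as a bright band whose width w along the lamella axis relates to
the plateau thickness d by d = w·sin(θ).  Tracking w frame by frame during
milling yields a thickness-versus-time series.  The method is reliable for
d between roughly 2000 and 400 nm; estimates outside that window are
flagged, not suppressed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import NoWedgeError

#: validity window of the geometric estimate (nm)
VALID_RANGE_NM = (400.0, 2000.0)


@dataclass(frozen=True)
class InstrumentGeometry:
    """Milling/imaging geometry of the coincident FIB-SEM light microscope."""

    fib_incidence_deg: float = 10.0
    sem_incidence_deg: float = 52.0
    mill_rate_nm_s: float = 2.4

    def __post_init__(self) -> None:
        if not (0 < self.fib_incidence_deg < 90):
            raise ValueError("fib_incidence_deg must be in (0, 90)")
        if self.mill_rate_nm_s <= 0:
            raise ValueError("mill_rate_nm_s must be positive")


@dataclass(frozen=True)
class WedgeGeometry:
    """Measured wedge width w, milling angle θ and derived thickness d."""

    w_um: float
    theta_deg: float
    d_nm: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.w_um < 0:
            raise ValueError("w_um must be >= 0")
        d = thickness_from_wedge(self.w_um, self.theta_deg)
        if self.d_nm is None:
            object.__setattr__(self, "d_nm", d)
        elif not math.isclose(self.d_nm, d, rel_tol=1e-6, abs_tol=1e-9):
            raise ValueError("d_nm inconsistent with w·sin(theta)")


@dataclass
class RlmSeries:
    """Time-ordered reflected-light frames with acquisition metadata."""

    frames: np.ndarray  # (n, y, x)
    timestamps_s: np.ndarray
    pixel_size_um: float
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, y, x) stack")
        if len(self.timestamps_s) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if np.any(np.diff(self.timestamps_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


def thickness_from_wedge(w_um: float, theta_deg: float):
    """Lamella thickness d = w·sin(θ) in nm from wedge width w (μm)."""
    w = np.asarray(w_um, dtype=float)
    if np.any(w < 0):
        raise ValueError("wedge width must be >= 0")
    if not 0 < theta_deg < 90:
        raise ValueError("milling angle must be in (0, 90) degrees")
    d = 1000.0 * w * math.sin(math.radians(theta_deg))
    return d if d.ndim else float(d)


def milling_angle_from_defocus(defocus_um: float, lamella_length_um: float) -> float:
    """Milling angle θ = arcsin(defocus / length) in degrees.

    The defocus between the two wedge ends over the full lamella length
    measures the actual milling angle (e.g. arcsin(4/22.4) = 10.2°).
    """
    if lamella_length_um <= 0:
        raise ValueError("lamella_length_um must be positive")
    if not 0 <= defocus_um <= lamella_length_um:
        raise ValueError("require 0 <= defocus <= lamella length")
    return math.degrees(math.asin(defocus_um / lamella_length_um))


@dataclass(frozen=True)
class WedgeWidthResult:
    """Foil-side peak width and detection metadata."""

    w_um: float
    peak_index: int
    peak_value: float
    background: float
    noise_sigma: float
    left_crossing_px: float
    right_crossing_px: float


def _profile(frame: np.ndarray, axis_spec: str) -> np.ndarray:
    # mean over the lamella width (x) leaves a profile along the length (y)
    frame = np.asarray(frame, dtype=float)
    if axis_spec == "y":
        return frame.mean(axis=1)
    if axis_spec == "x":
        return frame.mean(axis=0)
    raise ValueError("axis_spec must be 'y' (profile along rows) or 'x'")


def extract_wedge_width(
    frame: np.ndarray,
    pixel_size_um: float,
    axis_spec: str = "y",
    background_level: float | None = None,
    k_sigma: float = 3.0,
    peak_fraction: float = 0.5,
    foil_side: str = "low",
) -> WedgeWidthResult:
    """Width of the foil-side intensity peak in a reflected-light frame.

    The frame is averaged across the lamella width, the foil-side peak of
    the resulting profile is located, and its width is measured at
    ``peak_fraction`` (default half) of the peak height above background,
    with sub-pixel linear interpolation at the crossings.  Background and
    noise default to the profile median and a MAD-based sigma; a peak must
    exceed background + ``k_sigma``·sigma, else :class:`NoWedgeError` is
    raised (the wedge of a very thin lamella is no longer resolvable).

    ``foil_side`` selects which end of the profile holds the foil-side
    band: ``"low"`` (small y, default) or ``"high"``.
    """
    prof = _profile(frame, axis_spec)
    # two-pass background: exclude the candidate peak region (upper half of
    # the dynamic range) first, then take the median of what remains, so a
    # wedge band covering most of the field does not contaminate the estimate
    lo, hi = float(prof.min()), float(prof.max())
    outside = prof <= lo + 0.5 * (hi - lo)
    if background_level is None:
        bg = float(np.median(prof[outside])) if outside.any() else lo
    else:
        bg = float(background_level)
    resid = prof[outside] - np.median(prof[outside]) if outside.any() else prof - bg
    sigma = float(1.4826 * np.median(np.abs(resid)))
    if sigma == 0.0:
        sigma = float(np.std(resid))
    threshold = bg + k_sigma * sigma
    peaks, props = signal.find_peaks(prof, height=threshold)
    # plateau-topped peaks (rectangular bands) need plateau handling
    if peaks.size == 0:
        plateau, props = signal.find_peaks(prof, height=threshold, plateau_size=1)
        peaks = plateau
    if peaks.size == 0:
        raise NoWedgeError(
            f"no peak above background {bg:.3g} + {k_sigma}*sigma ({sigma:.3g})"
        )
    idx = int(peaks[0] if foil_side == "low" else peaks[-1])
    peak_val = float(prof[idx])
    level = bg + peak_fraction * (peak_val - bg)

    def _cross(start: int, step: int) -> float:
        i = start
        while 0 <= i + step < len(prof) and prof[i + step] >= level:
            i += step
        j = i + step
        if j < 0 or j >= len(prof):
            return float(i)  # peak touches the frame edge
        # linear interpolation between the last above-level and first below
        frac = (prof[i] - level) / (prof[i] - prof[j])
        return i + step * frac

    left = _cross(idx, -1)
    right = _cross(idx, +1)
    w_px = right - left
    return WedgeWidthResult(
        w_um=float(w_px * pixel_size_um),
        peak_index=idx,
        peak_value=peak_val,
        background=bg,
        noise_sigma=sigma,
        left_crossing_px=left,
        right_crossing_px=right,
    )


def thickness_time_series(
    series: RlmSeries,
    theta_deg: float,
    **wedge_kwargs,
) -> pd.DataFrame:
    """Per-frame wedge width and thickness versus milling time.

    Returns a DataFrame with columns ``t_s``, ``w_um``, ``d_nm`` and
    ``flag``.  Frames without a detectable wedge are flagged ``no-wedge``
    (NaN width), estimates outside the geometric validity window are
    flagged ``outside-validity``; nothing is dropped silently.  The
    attribute ``df.attrs["monotone_nonincreasing"]`` records whether the
    detected thicknesses only ever decrease, as physical milling demands.
    """
    rows = []
    for t, frame in zip(series.timestamps_s, series.frames):
        try:
            res = extract_wedge_width(frame, series.pixel_size_um, **wedge_kwargs)
            d = thickness_from_wedge(res.w_um, theta_deg)
            flag = ""
            if not VALID_RANGE_NM[0] <= d <= VALID_RANGE_NM[1]:
                flag = "outside-validity"
            rows.append((t, res.w_um, d, flag))
        except NoWedgeError:
            rows.append((t, np.nan, np.nan, "no-wedge"))
    df = pd.DataFrame(rows, columns=["t_s", "w_um", "d_nm", "flag"])
    d = df["d_nm"].dropna().to_numpy()
    df.attrs["monotone_nonincreasing"] = bool(np.all(np.diff(d) <= 1e-9)) if d.size else True
    return df
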