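"""EFTEM zero-loss log-ratio thickness mapping and map comparison.

The fraction of electrons that pass an energy filter's zero-loss window
decays exponentially with thickness t over the inelastic mean free path
λ_inel (≈320 nm for 300 keV in vitreous ice):  I/I0 = exp(−t/λ_inel).
Hence t = λ_inel·ln(I0/I) per pixel.  A baseline (the mean apparent
thickness over a vacuum region) is subtracted so holes read exactly zero,
which also removes any global exposure mismatch between the two images.
With the lamella pre-tilted by 10° the beam path through it exceeds the
lamella-normal thickness by 1/cos(tilt), so the map is multiplied by
cos(pre-tilt) to report normal thickness (the same projection the q4STEM
incidence correction applies to its path length).  Serves as the ground-truth benchmark for the in-situ methods.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import ThicknessMap


@dataclass(frozen=True)
class EftemParams:
    lambda_inel_nm: float = 320.0
    pixel_size_nm: float = 3.59
    pre_tilt_deg: float = 10.0

    def __post_init__(self) -> None:
        if self.lambda_inel_nm <= 0:
            raise ValueError("lambda_inel_nm must be positive")


@dataclass
class EftemPair:
    """Unfiltered (I0) / zero-loss (I) image pair with a vacuum region."""

    unfiltered: np.ndarray
    zero_loss: np.ndarray
    params: EftemParams
    vacuum_roi: tuple  # (slice, slice) or boolean mask

    def __post_init__(self) -> None:
        self.unfiltered = np.asarray(self.unfiltered, dtype=float)
        self.zero_loss = np.asarray(self.zero_loss, dtype=float)
        if self.unfiltered.shape != self.zero_loss.shape:
            raise ValueError("image pair must share one shape")

    def vacuum_mask(self) -> np.ndarray:
        sel = np.zeros(self.unfiltered.shape, dtype=bool)
        if isinstance(self.vacuum_roi, tuple) and not isinstance(
            self.vacuum_roi, np.ndarray
        ):
            sel[self.vacuum_roi] = True
        else:
            sel = np.asarray(self.vacuum_roi, dtype=bool)
        if not sel.any():
            raise ValueError("vacuum ROI is empty")
        return sel


def thickness_map(pair: EftemPair, tilt_correct: bool = True) -> ThicknessMap:
    """t = λ_inel·ln(I0/I), baseline-corrected and pre-tilt-corrected.

    Non-positive pixels are flagged NaN and excluded from the valid mask;
    after the baseline correction the vacuum region averages exactly zero.
    Thickness of valid pixels may come out slightly negative through noise
    around zero — such pixels are kept (clipping would bias the vacuum
    mean) but excluded from the validity mask.
    """
    I0, I = pair.unfiltered, pair.zero_loss
    good = (I0 > 0) & (I > 0)
    t = np.full(I.shape, np.nan)
    t[good] = pair.params.lambda_inel_nm * np.log(I0[good] / I[good])
    vac = pair.vacuum_mask() & good
    if not vac.any():
        raise ValueError("no valid pixels in the vacuum ROI")
    t -= np.nanmean(t[vac])
    if tilt_correct:
        t *= math.cos(math.radians(pair.params.pre_tilt_deg))
    # negative values from noise around zero stay in the array (excluding
    # them would bias vacuum statistics) but are outside the valid mask
    mask = good & (t >= 0)
    return ThicknessMap(
        np.where(good, t, np.nan),
        pixel_size_um=pair.params.pixel_size_nm / 1000.0,
        method="eftem",
        mask=mask,
        metadata={
            "lambda_inel_nm": pair.params.lambda_inel_nm,
            "pre_tilt_deg": pair.params.pre_tilt_deg if tilt_correct else 0.0,
        },
    )


def _block_mean(values: np.ndarray, factor: int) -> np.ndarray:
    ny, nx = values.shape
    ny2, nx2 = ny // factor, nx // factor
    v = values[: ny2 * factor, : nx2 * factor]
    return np.nanmean(v.reshape(ny2, factor, nx2, factor), axis=(1, 3))


@dataclass(frozen=True)
class MapComparison:
    mean_diff_nm: float
    sd_diff_nm: float
    profile_x_nm: np.ndarray  # mean over rows -> profile along columns
    profile_y_nm: np.ndarray  # mean over columns -> profile along rows
    pixel_size_um: float


def compare_maps(
    map_a: ThicknessMap,
    map_b: ThicknessMap,
    roi: tuple | np.ndarray | None = None,
) -> MapComparison:
    """Quantitative difference between two registered thickness maps.

    Thickness is a local mean quantity, so the finer map is block-averaged
    down to the coarser grid (integer factor) before differencing.  Mean
    and SD of (a − b) over the ROI plus mean line profiles of the
    difference along both axes are returned.
    """
    a, pa = map_a.values_nm, map_a.pixel_size_um
    b, pb = map_b.values_nm, map_b.pixel_size_um
    if pa != pb:
        if pa < pb:
            factor = round(pb / pa)
            a = _block_mean(a, factor)
            pa = pb
        else:
            factor = round(pa / pb)
            b = _block_mean(b, factor)
    ny = min(a.shape[0], b.shape[0])
    nx = min(a.shape[1], b.shape[1])
    diff = a[:ny, :nx] - b[:ny, :nx]
    sel = np.isfinite(diff)
    if roi is not None:
        roi_mask = np.zeros(diff.shape, dtype=bool)
        if isinstance(roi, tuple) and not isinstance(roi, np.ndarray):
            roi_mask[roi] = True
        else:
            roi_mask = np.asarray(roi, dtype=bool)[:ny, :nx]
        sel &= roi_mask
    if not sel.any():
        raise ValueError("empty ROI")
    d = diff[sel]
    masked = np.where(sel, diff, np.nan)
    with np.errstate(invalid="ignore"):
        prof_x = np.nanmean(masked, axis=0)
        prof_y = np.nanmean(masked, axis=1)
    return MapComparison(
        mean_diff_nm=float(d.mean()),
        sd_diff_nm=float(d.std()),
        profile_x_nm=prof_x,
        profile_y_nm=prof_y,
        pixel_size_um=pa,
    )
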