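"""Axial coordinate correction under refractive-index mismatch (RIM).

A dry objective (index ``n1``, typically 1.0) focusing into vitreous ice
(``n2`` ≈ 1.28 at 109 K) compresses the measured axial coordinate: a
fluorescent emitter at actual depth ``z_actual`` below the vacuum-specimen
interface is observed at a shallower nominal depth ``z_nominal``.  Within
the linear regime (emitters no deeper than ~9 μm for NA 0.85) the two are
related by a constant scaling factor ``S = z_actual / z_nominal``.

The high-NA scaling factor is computed by averaging the geometric ray
ratio tan(θ1)/tan(θ2) uniformly over the aperture, with
``sin θ2 = (n1/n2)·sin θ1`` and ``sin θ1 ∈ (0, NA/n1]``.  For a single ray
this ratio reduces to sqrt((n2² − sin²θ1)/(n1² − sin²θ1)), which runs from
the paraxial bound ``n2/n1`` at the axis to the marginal-ray value at the
aperture edge; the aperture mean lies in between.  The averaging scheme is
exposed so the paraxial and marginal conventions remain selectable.

The focal shift (z_actual − z_nominal) grows linearly with depth.  Because
the compression always places the emitter *deeper* than measured, a rough
milling pattern centred on the nominal position can be made safe by
placing its bottom edge a small margin below the coincident point and its
top edge the worst-case focal shift above it (asymmetric pattern).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidApertureError

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)


@dataclass(frozen=True)
class AxialScalingModel:
    """Optical configuration for RIM axial scaling.

    ``averaging`` selects how the ray ratio is reduced over the aperture:
    ``"aperture_mean"`` (uniform mean over sin θ1, default), ``"paraxial"``
    (n2/n1) or ``"marginal"`` (edge ray only).  ``depth_convention``
    states whether depths passed to :func:`focal_shift` are actual
    (``"actual"``, default) or nominal (``"nominal"``) emitter depths.
    """

    na: float
    n1: float = 1.0
    n2: float = 1.28
    linear_limit_um: float = 9.0
    averaging: str = "aperture_mean"
    depth_convention: str = "actual"

    def __post_init__(self) -> None:
        if self.na < 0:
            raise InvalidApertureError("numerical aperture must be >= 0")
        if self.na >= self.n1:
            raise InvalidApertureError(
                f"NA {self.na} >= n1 {self.n1}: dry-lens geometry impossible"
            )
        if not (0 < self.n1 <= self.n2):
            raise ValueError("require 0 < n1 <= n2 for a compressive RIM")
        if self.averaging not in ("aperture_mean", "paraxial", "marginal"):
            raise ValueError(f"unknown averaging {self.averaging!r}")
        if self.depth_convention not in ("actual", "nominal"):
            raise ValueError(f"unknown depth convention {self.depth_convention!r}")


def _ray_ratio(sin_t1: np.ndarray, n1: float, n2: float) -> np.ndarray:
    return np.sqrt((n2**2 - sin_t1**2) / (n1**2 - sin_t1**2))


def scaling_factor(model: AxialScalingModel) -> float:
    """Axial scaling factor S = z_actual / z_nominal (dimensionless, ≥ n2/n1)."""
    if model.n1 == model.n2:
        return 1.0
    if model.averaging == "paraxial" or model.na == 0:
        return model.n2 / model.n1
    s_max = model.na / model.n1
    if model.averaging == "marginal":
        return float(_ray_ratio(np.array(s_max), model.n1, model.n2))
    # uniform mean of the ray ratio over sin θ1 ∈ (0, NA/n1]
    s = 0.5 * s_max * (_GL_NODES + 1.0)
    vals = _ray_ratio(s, model.n1, model.n2)
    return float(np.sum(_GL_WEIGHTS * vals) * 0.5)


def nominal_to_actual(model: AxialScalingModel, z_nominal_um):
    """Map measured (nominal) depth to actual depth: z_actual = S·z_nominal."""
    return np.asarray(z_nominal_um, dtype=float) * scaling_factor(model)


def actual_to_nominal(model: AxialScalingModel, z_actual_um):
    """Inverse of :func:`nominal_to_actual`."""
    return np.asarray(z_actual_um, dtype=float) / scaling_factor(model)


def focal_shift(model: AxialScalingModel, depth_um):
    """Focal shift z_actual − z_nominal (μm) for an emitter at ``depth_um``.

    The depth is interpreted per ``model.depth_convention``.  Exactly
    linear in depth; zero at the interface.  Depths beyond the linear
    limit raise a ``UserWarning`` (the linear model is untested there) but
    still return the linear extrapolation.
    """
    depth = np.asarray(depth_um, dtype=float)
    if np.any(depth < 0):
        raise ValueError("emitter depth must be >= 0")
    if np.any(depth > model.linear_limit_um):
        warnings.warn(
            f"depth beyond linear regime ({model.linear_limit_um} um); "
            "linear axial scaling may not hold",
            stacklevel=2,
        )
    s = scaling_factor(model)
    if model.depth_convention == "actual":
        shift = depth * (1.0 - 1.0 / s)
    else:
        shift = depth * (s - 1.0)
    return shift if shift.ndim else float(shift)


@dataclass(frozen=True)
class PatternPlacement:
    """Asymmetric rough-milling pattern offsets around the coincident point."""

    bottom_offset_um: float
    top_offset_um: float

    def __post_init__(self) -> None:
        if self.bottom_offset_um <= 0:
            raise ValueError("bottom_offset_um must be positive")
        if self.top_offset_um < self.bottom_offset_um:
            raise ValueError("top offset must be >= bottom offset (asymmetry)")


def place_asymmetric_pattern(
    model: AxialScalingModel,
    max_nominal_depth_um: float | None = None,
    bottom_margin_um: float = 0.3,
) -> PatternPlacement:
    """Place the rough-milling pattern so the fluorescent target is enclosed.

    The bottom pattern sits ``bottom_margin_um`` (default 0.3 μm, "a few
    hundred nanometres") below the coincident point: the RIM compression
    guarantees the emitter is never shallower than measured.  The top
    pattern adds the worst-case focal shift for an emitter whose nominal
    position coincides with the coincident point, ``max_nominal ·(S − 1)``.
    ``max_nominal_depth_um`` defaults to the nominal depth whose actual
    depth equals the linear limit (linear_limit / S).
    """
    s = scaling_factor(model)
    if max_nominal_depth_um is None:
        max_nominal_depth_um = model.linear_limit_um / s
    if max_nominal_depth_um <= 0:
        raise ValueError("max_nominal_depth_um must be positive")
    worst_shift = max_nominal_depth_um * (s - 1.0)
    return PatternPlacement(
        bottom_offset_um=bottom_margin_um,
        top_offset_um=bottom_margin_um + worst_shift,
    )


def shift_table(model: AxialScalingModel, depths_um) -> "np.ndarray":
    """Vector of focal shifts for a grid of depths (μm); used by the CLI."""
    return np.asarray([focal_shift(model, d) for d in np.atleast_1d(depths_um)])
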