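"""Lamella thickness from transmitted-electron scattering patterns (q4STEM).

With the SEM in spot mode, the transmitted 30 keV beam produces a
scattering pattern on a scintillator a camera length D (≈300 μm) below
the sample; the optical microscope images the scintillation light.  The
pattern is radially integrated about the beam centre, split at the
bright-field disc semi-angle into virtual bright-field (BF) and
dark-field (DF) sums, and the DF/BF ratio — which grows monotonically
with thickness — is inverted against a Monte-Carlo lookup table computed
for the same beam energy and material.  The most common scattering angle
serves as an independent consistency check.  No per-session calibration
is needed: geometry (D, pixel size, centre) fixes the angular scale via
θ = arctan(r/D).

The electron beam meets the lamella at non-normal incidence (52° in the
reference geometry), so the measured DF/BF ratio reflects the beam *path
length* through the lamella; the thickness along the lamella normal is
path·cos(incidence).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import OutOfRangeError, TableQualityError
from . import mc

#: default angular acceptance of the scintillator, mrad
DEFAULT_MAX_ANGLE_MRAD = 218.0
#: default virtual BF disc semi-angle, mrad (overridable per measurement,
#: or derived from a vacuum beam exposure via bf_cutoff_from_vacuum)
DEFAULT_BF_CUTOFF_MRAD = 30.0


@dataclass(frozen=True)
class DetectorGeometry:
    """Scintillator geometry: camera length D, pixel size, beam centre."""

    pixel_size_um: float
    center_px: tuple[float, float]
    specimen_to_scintillator_um: float = 300.0
    max_angle_mrad: float = DEFAULT_MAX_ANGLE_MRAD

    def __post_init__(self) -> None:
        if self.specimen_to_scintillator_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("geometry lengths must be positive")


def pixel_to_angle(r_um, geometry: DetectorGeometry):
    """Scattering angle (mrad) of a radius r (μm) on the scintillator."""
    r = np.asarray(r_um, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be >= 0")
    a = np.arctan(r / geometry.specimen_to_scintillator_um) * 1000.0
    return a if a.ndim else float(a)


@dataclass
class ScatterPattern:
    """2D scattering-pattern image with angular calibration."""

    image: np.ndarray
    geometry: DetectorGeometry
    beam_energy_keV: float = 30.0
    probe_position: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("pattern image must be 2D")
        if np.any(self.image < 0):
            raise ValueError("pattern intensities must be >= 0")
        r, c = self.geometry.center_px
        ny, nx = self.image.shape
        if not (0 <= r < ny and 0 <= c < nx):
            raise ValueError("beam centre outside the image")


@dataclass
class RadialProfile:
    """Radially integrated intensity versus scattering angle."""

    angle_mrad: np.ndarray  # bin centres, strictly increasing
    intensity: np.ndarray  # summed counts per bin
    bin_width_mrad: float
    bf_cutoff_mrad: float | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.angle_mrad) <= 0):
            raise ValueError("angle bins must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")


def radial_profile(
    pattern: ScatterPattern,
    n_bins: int = 64,
    bf_cutoff_mrad: float | None = None,
) -> RadialProfile:
    """Sum the pattern into equal-angle annular bins about the beam centre.

    Pixels beyond the angular acceptance are excluded; within it, total
    counts are conserved exactly (sum of profile == sum of masked image).
    """
    geom = pattern.geometry
    ny, nx = pattern.image.shape
    rows = (np.arange(ny) - geom.center_px[0])[:, None]
    cols = (np.arange(nx) - geom.center_px[1])[None, :]
    r_um = np.hypot(rows, cols) * geom.pixel_size_um
    ang = pixel_to_angle(r_um, geom)
    width = geom.max_angle_mrad / n_bins
    idx = np.minimum((ang / width).astype(np.intp), n_bins)  # n_bins = beyond
    inside = ang <= geom.max_angle_mrad
    idx = np.where(inside, np.minimum(idx, n_bins - 1), n_bins)
    counts = np.bincount(idx.ravel(), weights=pattern.image.ravel(), minlength=n_bins + 1)
    centers = (np.arange(n_bins) + 0.5) * width
    return RadialProfile(
        angle_mrad=centers,
        intensity=counts[:n_bins],
        bin_width_mrad=width,
        bf_cutoff_mrad=bf_cutoff_mrad,
    )


def df_bf_ratio(profile: RadialProfile, bf_cutoff_mrad: float | None = None) -> float:
    """Integrated dark-field / bright-field ratio of a radial profile."""
    cutoff = bf_cutoff_mrad if bf_cutoff_mrad is not None else profile.bf_cutoff_mrad
    if cutoff is None:
        cutoff = DEFAULT_BF_CUTOFF_MRAD
    bf = float(profile.intensity[profile.angle_mrad <= cutoff].sum())
    df = float(profile.intensity[profile.angle_mrad > cutoff].sum())
    if bf == 0:
        raise ZeroDivisionError("bright-field sum is zero: beam not captured")
    return df / bf


@dataclass(frozen=True)
class PeakAngle:
    angle_mrad: float
    ambiguous: bool = False


def most_common_angle(profile: RadialProfile) -> PeakAngle:
    """Angle of the peak of the per-solid-angle corrected distribution.

    The raw annular sums are divided by the annulus solid angle before
    locating the maximum; a parabolic fit refines the peak to sub-bin
    resolution.  A flat profile or a tie (second bin within 1e-12 of the
    maximum) sets ``ambiguous`` and the lower-angle peak is returned.
    """
    if profile.intensity.sum() == 0:
        return PeakAngle(angle_mrad=float("nan"), ambiguous=True)
    theta = profile.angle_mrad / 1000.0
    half = profile.bin_width_mrad / 2000.0
    solid = np.cos(np.maximum(theta - half, 0.0)) - np.cos(theta + half)
    dens = profile.intensity / solid
    top = dens.max()
    peaks = np.flatnonzero(np.isclose(dens, top, rtol=1e-12, atol=0.0))
    ambiguous = len(peaks) > 1 or np.allclose(dens, dens[0])
    k = int(peaks[0])
    angle = profile.angle_mrad[k]
    if 0 < k < len(dens) - 1 and not ambiguous:
        y0, y1, y2 = dens[k - 1], dens[k], dens[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            angle = angle + 0.5 * profile.bin_width_mrad * (y0 - y2) / denom
    return PeakAngle(angle_mrad=float(angle), ambiguous=bool(ambiguous))


def bf_cutoff_from_vacuum(pattern: ScatterPattern, containment: float = 0.99) -> float:
    """BF disc semi-angle from an empty-hole (vacuum) beam exposure.

    Returns the angle containing ``containment`` (default 99%) of the
    unscattered-beam intensity.
    """
    prof = radial_profile(pattern, n_bins=256)
    cum = np.cumsum(prof.intensity)
    if cum[-1] == 0:
        raise ZeroDivisionError("vacuum pattern carries no intensity")
    cum = cum / cum[-1]
    k = int(np.searchsorted(cum, containment))
    return float(prof.angle_mrad[min(k, len(cum) - 1)] + prof.bin_width_mrad / 2)


# --------------------------------------------------------------------------


@dataclass
class McTable:
    """Thickness → DF/BF lookup from Monte-Carlo simulation.

    The ratio must increase strictly with thickness over the grid, which
    is what makes the inversion well posed; build_table rejects tables
    where counting noise breaks monotonicity.
    """

    thickness_nm: np.ndarray
    df_bf_ratio: np.ndarray
    ratio_se: np.ndarray
    most_common_angle_mrad: np.ndarray
    beam_energy_keV: float
    bf_cutoff_mrad: float
    max_angle_mrad: float
    n_electrons: int
    seed: int
    material: str = f"amorphous H2O, {mc.DEFAULT_DENSITY_G_CM3} g/cm3"

    def __post_init__(self) -> None:
        self.thickness_nm = np.asarray(self.thickness_nm, dtype=float)
        self.df_bf_ratio = np.asarray(self.df_bf_ratio, dtype=float)
        if np.any(np.diff(self.df_bf_ratio) <= 0):
            raise TableQualityError(
                "DF/BF ratio not strictly increasing with thickness; "
                "increase n_electrons to beat counting noise"
            )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        header = (
            f"# beam_energy_keV: {self.beam_energy_keV}\n"
            f"# bf_cutoff_mrad: {self.bf_cutoff_mrad}\n"
            f"# max_angle_mrad: {self.max_angle_mrad}\n"
            f"# n_electrons: {self.n_electrons}\n"
            f"# seed: {self.seed}\n"
            f"# material: {self.material}\n"
        )
        df = pd.DataFrame(
            {
                "thickness_nm": self.thickness_nm,
                "df_bf_ratio": self.df_bf_ratio,
                "ratio_se": self.ratio_se,
                "most_common_angle_mrad": self.most_common_angle_mrad,
            }
        )
        path.write_text(header + df.to_csv(index=False))
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "McTable":
        path = Path(path)
        meta = {}
        lines = path.read_text().splitlines()
        n_header = 0
        for line in lines:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
        df = pd.read_csv(path, skiprows=n_header)
        return cls(
            thickness_nm=df["thickness_nm"].to_numpy(),
            df_bf_ratio=df["df_bf_ratio"].to_numpy(),
            ratio_se=df["ratio_se"].to_numpy(),
            most_common_angle_mrad=df["most_common_angle_mrad"].to_numpy(),
            beam_energy_keV=float(meta["beam_energy_keV"]),
            bf_cutoff_mrad=float(meta["bf_cutoff_mrad"]),
            max_angle_mrad=float(meta["max_angle_mrad"]),
            n_electrons=int(meta["n_electrons"]),
            seed=int(meta["seed"]),
            material=meta.get("material", ""),
        )


def simulated_ratio(
    result: mc.McResult,
    bf_cutoff_mrad: float,
    max_angle_mrad: float = DEFAULT_MAX_ANGLE_MRAD,
) -> tuple[float, float]:
    """(DF/BF ratio, standard error) from simulated exit angles.

    Only transmitted electrons within the angular acceptance contribute,
    mirroring what the detector collects.
    """
    theta = result.exit_polar_rad[result.label == mc.TRANSMITTED] * 1000.0
    theta = theta[theta <= max_angle_mrad]
    n_df = int((theta > bf_cutoff_mrad).sum())
    n_bf = int((theta <= bf_cutoff_mrad).sum())
    if n_bf == 0:
        raise ZeroDivisionError("no bright-field electrons in simulation")
    ratio = n_df / n_bf
    se = ratio * math.sqrt(1.0 / max(n_df, 1) + 1.0 / n_bf) if n_df else 1.0 / n_bf
    return ratio, se


def build_table(
    thickness_grid,
    beam_energy_keV: float = 30.0,
    n_electrons: int = 20000,
    seed: int = 0,
    bf_cutoff_mrad: float = DEFAULT_BF_CUTOFF_MRAD,
    max_angle_mrad: float = DEFAULT_MAX_ANGLE_MRAD,
) -> McTable:
    """Simulate the DF/BF ratio and most-common angle on a thickness grid.

    One independent child seed per grid point keeps runs reproducible and
    uncorrelated.  Raises :class:`TableQualityError` if the resulting
    ratio is not strictly increasing.
    """
    thickness_grid = np.asarray(thickness_grid, dtype=float)
    ratios, ses, mcas = [], [], []
    for i, t in enumerate(thickness_grid):
        res = mc.mc_simulate(
            float(t), beam_energy_keV, n_electrons, seed=seed * 100003 + i
        )
        ratio, se = simulated_ratio(res, bf_cutoff_mrad, max_angle_mrad)
        theta = res.exit_polar_rad[res.label == mc.TRANSMITTED] * 1000.0
        theta = theta[theta <= max_angle_mrad]
        if theta.size == 0 or t == 0:
            mca = 0.0
        else:
            hist, edges = np.histogram(theta, bins=64, range=(0, max_angle_mrad))
            centers = 0.5 * (edges[:-1] + edges[1:])
            prof = RadialProfile(centers, hist.astype(float), edges[1] - edges[0])
            mca = most_common_angle(prof).angle_mrad
        ratios.append(ratio)
        ses.append(se)
        mcas.append(mca)
    return McTable(
        thickness_nm=thickness_grid,
        df_bf_ratio=np.array(ratios),
        ratio_se=np.array(ses),
        most_common_angle_mrad=np.array(mcas),
        beam_energy_keV=beam_energy_keV,
        bf_cutoff_mrad=bf_cutoff_mrad,
        max_angle_mrad=max_angle_mrad,
        n_electrons=n_electrons,
        seed=seed,
    )


@dataclass(frozen=True)
class Q4StemResult:
    d_nm: float
    path_length_nm: float
    ratio: float
    most_common_angle_mrad: float
    table_angle_mrad: float
    flags: tuple[str, ...] = ()


def thickness_from_pattern(
    pattern: ScatterPattern,
    table: McTable,
    incidence_deg: float = 52.0,
    n_bins: int = 256,
) -> Q4StemResult:
    """Invert the DF/BF ratio of a pattern against a Monte-Carlo table.

    The monotone interpolation of ratio → thickness yields the beam path
    length; the lamella-normal thickness is path·cos(incidence).  The
    measured most-common angle is reported next to the table's value at
    the recovered thickness as a consistency check.  Ratios outside the
    table range raise :class:`OutOfRangeError`.
    """
    prof = radial_profile(pattern, n_bins=n_bins, bf_cutoff_mrad=table.bf_cutoff_mrad)
    ratio = df_bf_ratio(prof)
    lo, hi = table.df_bf_ratio[0], table.df_bf_ratio[-1]
    if not lo <= ratio <= hi:
        raise OutOfRangeError(
            f"DF/BF ratio {ratio:.3g} outside table range [{lo:.3g}, {hi:.3g}]"
        )
    path = float(np.interp(ratio, table.df_bf_ratio, table.thickness_nm))
    d = path * math.cos(math.radians(incidence_deg))
    mca = most_common_angle(prof)
    table_mca = float(np.interp(path, table.thickness_nm, table.most_common_angle_mrad))
    flags = []
    if mca.ambiguous:
        flags.append("ambiguous-peak")
    if path > 1000.0:
        flags.append("beyond-validity")
    return Q4StemResult(
        d_nm=d,
        path_length_nm=path,
        ratio=ratio,
        most_common_angle_mrad=mca.angle_mrad,
        table_angle_mrad=table_mca,
        flags=tuple(flags),
    )


def thickness_line_scan(
    patterns: list[ScatterPattern],
    table: McTable,
    incidence_deg: float = 52.0,
) -> pd.DataFrame:
    """Map :func:`thickness_from_pattern` over an ordered probe sequence.

    Returns a DataFrame with one row per probe position; failed inversions
    are flagged, not dropped.
    """
    if not patterns:
        raise ValueError("empty pattern list")
    rows = []
    for i, p in enumerate(patterns):
        position = p.probe_position if p.probe_position is not None else (i, 0)
        try:
            res = thickness_from_pattern(p, table, incidence_deg)
            rows.append(
                (i, position[0], position[1], res.d_nm, res.ratio, ";".join(res.flags))
            )
        except (OutOfRangeError, ZeroDivisionError) as exc:
            rows.append((i, position[0], position[1], np.nan, np.nan, f"error:{exc}"))
    return pd.DataFrame(
        rows, columns=["index", "pos_x", "pos_y", "d_nm", "df_bf_ratio", "flag"]
    )
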