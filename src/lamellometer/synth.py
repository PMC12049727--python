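"""Synthetic-data generators with known ground truth.

Every measurement modality the package analyses can be emulated from a
2.5D lamella phantom (a thickness field, not a volume): reflected-light
milling series driven by the thin-film reflectivity model, per-probe
electron scattering patterns sampled from the Monte-Carlo transport, and
EFTEM unfiltered/zero-loss pairs from the exponential zero-loss law.
Generators always return their ground truth next to the rendered data,
and fixed seeds give bit-identical output.

Default study conditions follow the reference workflow: 10° milling
angle, 2.4 nm/s thinning rate, λ = 463/542/632 nm reflected-light
channels, 30 keV electrons, 320 nm inelastic mean free path.  Noise
defaults: additive Gaussian at 2% of dynamic range for RLM frames, pure
counting statistics for scattering patterns, 1% multiplicative for EFTEM.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import mc, tfi
from .eftem import EftemPair, EftemParams
from .q4stem import DetectorGeometry, ScatterPattern
from .rlm import RlmSeries


@dataclass
class LamellaPhantom:
    """Ground-truth lamella: thickness field plus region masks.

    The thickness field is a trapezoid along y: linear wedges at both
    ends whose slope matches the milling angle (footprint w = d/sinθ),
    a flat centre with an optional leading-to-trailing linear ramp, and
    zero-thickness background beyond the wedges.  ``pt_layer_mask`` marks
    the platinum-rich GIS band at the trailing (high-y) edge.
    """

    thickness_nm: np.ndarray
    pixel_size_um: float
    theta_deg: float
    pt_layer_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    envelope_nm: np.ndarray = field(default=None)  # type: ignore[assignment]
    plateau_nm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.thickness_nm = np.asarray(self.thickness_nm, dtype=float)
        if np.any(self.thickness_nm < 0):
            raise ValueError("phantom thickness must be >= 0")
        if self.pt_layer_mask is None:
            self.pt_layer_mask = np.zeros(self.thickness_nm.shape, dtype=bool)
        if self.envelope_nm is None:
            self.envelope_nm = self.thickness_nm.copy()
        if self.plateau_nm is None:
            self.plateau_nm = self.thickness_nm.copy()

    @property
    def lamella_mask(self) -> np.ndarray:
        return self.thickness_nm > 0

    @property
    def wedge_mask(self) -> np.ndarray:
        """Pixels whose thickness is wedge-limited rather than plateau-limited."""
        return (self.envelope_nm < self.plateau_nm - 1e-9) & self.lamella_mask

    def thinned(self, removed_nm: float) -> np.ndarray:
        """Thickness field after removing ``removed_nm`` of material."""
        return np.clip(self.envelope_nm - removed_nm, 0.0, None)


def make_phantom(
    length_um: float = 30.0,
    width_um: float = 10.0,
    center_thickness_nm: float = 600.0,
    theta_deg: float = 10.0,
    ramp_nm: float = 0.0,
    pixel_size_um: float = 0.1,
    margin_um: float = 2.0,
    pt_layer: bool = True,
) -> LamellaPhantom:
    """Build a wedge-ended lamella phantom.

    The wedge slope is sin(θ) (nm of thickness per nm along y), so the
    foil-side wedge footprint obeys w = d / sin(θ); e.g. a 430 nm centre
    at θ = 10° gives w ≈ 2.48 μm.  ``ramp_nm`` tilts the plateau linearly
    from leading (+ramp/2) to trailing (−ramp/2) edge, mimicking the
    diminished ion flux along the milling direction.
    """
    if min(length_um, width_um, pixel_size_um) <= 0:
        raise ValueError("dimensions must be positive")
    if center_thickness_nm - abs(ramp_nm) / 2 < 0:
        raise ValueError("centre thinner than zero after applying the ramp")
    ny = int(round(length_um / pixel_size_um))
    nx = int(round(width_um / pixel_size_um))
    y_um = (np.arange(ny) + 0.5) * pixel_size_um
    slope_nm_per_um = 1000.0 * math.sin(math.radians(theta_deg))
    y0, y1 = margin_um, length_um - margin_um
    rise = slope_nm_per_um * (y_um - y0)
    fall = slope_nm_per_um * (y1 - y_um)
    frac = np.clip((y_um - y0) / max(y1 - y0, 1e-12), 0.0, 1.0)
    plateau = center_thickness_nm + ramp_nm * (0.5 - frac)
    envelope = np.minimum(np.minimum(rise, fall), plateau)
    profile = np.clip(envelope, 0.0, None)
    thickness = np.repeat(profile[:, None], nx, axis=1)
    envelope2d = np.repeat(envelope[:, None], nx, axis=1)
    pt_mask = np.zeros((ny, nx), dtype=bool)
    if pt_layer:
        trailing = (fall < plateau) & (profile > 0)
        pt_mask[trailing, :] = True
    return LamellaPhantom(
        thickness_nm=thickness,
        pixel_size_um=pixel_size_um,
        theta_deg=theta_deg,
        pt_layer_mask=pt_mask,
        envelope_nm=envelope2d,
        plateau_nm=np.repeat(plateau[:, None], nx, axis=1),
    )


@dataclass
class MillSimulation:
    """Constant-rate thinning of a phantom with an imaging noise model."""

    phantom: LamellaPhantom
    mill_rate_nm_s: float = 2.4
    frame_interval_s: float = 10.0
    n_frames: int = 20
    noise_sigma_frac: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mill_rate_nm_s <= 0 or self.frame_interval_s <= 0:
            raise ValueError("rate and frame interval must be positive")

    def truth_stack(self) -> tuple[np.ndarray, np.ndarray]:
        """(timestamps_s, thickness stack); non-increasing by construction."""
        t_s = np.arange(self.n_frames) * self.frame_interval_s
        stack = np.stack(
            [self.phantom.thinned(self.mill_rate_nm_s * t) for t in t_s]
        )
        return t_s, stack


def render_rlm_series(
    sim: MillSimulation,
    params: tfi.TfiParams,
    background_level: float | None = None,
    wedge_boost: float | None = None,
    pt_level: float | None = None,
) -> tuple[RlmSeries, np.ndarray]:
    """Reflected-light frames of a thinning lamella plus per-frame truth.

    Plateau pixels carry the thin-film reflectivity of their local
    thickness; the wedge footprints render as bright bands (specular
    foil-side reflection) so the geometric pipeline can measure their
    width; the Pt GIS mask renders at a high constant level and the
    background at a low constant.  Additive Gaussian noise at
    ``noise_sigma_frac`` of the clean dynamic range is applied per pixel.
    """
    rng = np.random.default_rng(sim.seed)
    ph = sim.phantom
    bg = background_level if background_level is not None else 0.1 * params.r_mea
    boost = wedge_boost if wedge_boost is not None else params.r_mea + 3 * params.r_A
    pt = pt_level if pt_level is not None else params.r_mea + 4 * params.r_A
    t_s, truth = sim.truth_stack()
    frames = np.empty_like(truth)
    wedge_static = ph.wedge_mask
    for k in range(sim.n_frames):
        th = truth[k]
        frame = np.full(th.shape, bg)
        lam = th > 0
        frame[lam] = tfi.reflectivity(th[lam], params)
        frame[wedge_static & lam] = boost
        frame[ph.pt_layer_mask & lam] = pt
        span = frame.max() - frame.min()
        if sim.noise_sigma_frac > 0:
            frame = frame + rng.normal(0.0, sim.noise_sigma_frac * span, frame.shape)
        frames[k] = frame
    series = RlmSeries(
        frames=frames,
        timestamps_s=t_s,
        pixel_size_um=ph.pixel_size_um,
        wavelength_nm=params.wavelength_nm,
    )
    return series, truth


def default_detector_geometry(
    n_px: int = 128,
    specimen_to_scintillator_um: float = 300.0,
    max_angle_mrad: float = 218.0,
) -> DetectorGeometry:
    """Detector geometry whose image edge corresponds to the acceptance angle."""
    half = (n_px - 1) / 2.0
    pixel_size = specimen_to_scintillator_um * math.tan(max_angle_mrad / 1000.0) / half
    return DetectorGeometry(
        pixel_size_um=pixel_size,
        center_px=(half, half),
        specimen_to_scintillator_um=specimen_to_scintillator_um,
        max_angle_mrad=max_angle_mrad,
    )


def render_scatter_patterns(
    phantom: LamellaPhantom,
    probe_positions_px: list[tuple[int, int]],
    geometry: DetectorGeometry | None = None,
    dose: int = 2000,
    seed: int = 0,
    beam_energy_keV: float = 30.0,
) -> tuple[list[ScatterPattern], np.ndarray]:
    """Per-probe scattering-pattern images plus the local truth thickness.

    For each probe position ``dose`` electron trajectories are sampled at
    the local ground-truth thickness; transmitted exit angles are given a
    uniform azimuth, projected to the scintillator via r = D·tan(θ) and
    binned into an image.  Counting (Poisson) statistics arise implicitly
    from the finite electron count.
    """
    if geometry is None:
        geometry = default_detector_geometry()
    ny, nx = phantom.thickness_nm.shape
    n_img = int(2 * geometry.center_px[0] + 1)
    truth = []
    patterns = []
    for i, (pr, pc) in enumerate(probe_positions_px):
        if not (0 <= pr < ny and 0 <= pc < nx):
            raise ValueError(f"probe {(pr, pc)} outside phantom")
        th = float(phantom.thickness_nm[pr, pc])
        truth.append(th)
        res = mc.mc_simulate(
            th, beam_energy_keV, n_electrons=dose, seed=seed * 99991 + i
        )
        rng = np.random.default_rng(seed * 77003 + i)
        theta = res.exit_polar_rad[res.label == mc.TRANSMITTED]
        r_um = geometry.specimen_to_scintillator_um * np.tan(theta)
        phi = rng.random(theta.size) * 2 * np.pi
        row = geometry.center_px[0] + r_um * np.sin(phi) / geometry.pixel_size_um
        col = geometry.center_px[1] + r_um * np.cos(phi) / geometry.pixel_size_um
        img, _, _ = np.histogram2d(
            row, col, bins=n_img, range=((0, n_img), (0, n_img))
        )
        patterns.append(
            ScatterPattern(
                image=img,
                geometry=geometry,
                beam_energy_keV=beam_energy_keV,
                probe_position=(pr, pc),
            )
        )
    return patterns, np.asarray(truth)


def render_eftem_pair(
    phantom: LamellaPhantom,
    params: EftemParams | None = None,
    i0_level: float = 1000.0,
    noise_frac: float = 0.01,
    seed: int = 0,
    tilted: bool = False,
) -> tuple[EftemPair, np.ndarray]:
    """Unfiltered/zero-loss pair from the exponential zero-loss law.

    I0 is uniform and I = I0·exp(−t/λ_inel); both images receive
    independent multiplicative Gaussian noise of relative width
    ``noise_frac``.  The phantom's zero-thickness background supplies the
    vacuum ROI for baseline correction.  With ``tilted`` the beam path is
    lengthened by 1/cos(pre_tilt), matching what the pre-tilt correction
    in the analysis undoes.
    """
    if params is None:
        params = EftemParams(
            pixel_size_nm=phantom.pixel_size_um * 1000.0, pre_tilt_deg=0.0
        )
    rng = np.random.default_rng(seed)
    t = phantom.thickness_nm
    path = t / math.cos(math.radians(params.pre_tilt_deg)) if tilted else t
    I0 = np.full(t.shape, float(i0_level))
    I = i0_level * np.exp(-path / params.lambda_inel_nm)
    if noise_frac > 0:
        I0 = I0 * (1.0 + rng.normal(0.0, noise_frac, t.shape))
        I = I * (1.0 + rng.normal(0.0, noise_frac, t.shape))
    vacuum_rows = np.flatnonzero(~t.any(axis=1))
    if vacuum_rows.size == 0:
        raise ValueError("phantom has no vacuum region for the baseline")
    roi = (slice(vacuum_rows[0], vacuum_rows[0] + max(1, vacuum_rows.size // 2)),
           slice(None))
    pair = EftemPair(unfiltered=I0, zero_loss=I, params=params, vacuum_roi=roi)
    return pair, t.copy()
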