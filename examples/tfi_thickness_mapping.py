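"""Refine thickness to nanometre scale with thin-film interference.

Part 1 fits the thickness offset of a single-point reflectivity trace
recorded during constant-rate thinning (the timestamps fix the thickness
decrements, the interference fringes fix the absolute offset).  Part 2
refines a noisy per-pixel map around a geometric initial estimate and
reports the thickness uniformity (one standard deviation).
"""
import numpy as np

from lamellometer import TfiParams, ThicknessMap, fit_thickness_map, fit_trace, reflectivity

params = TfiParams(wavelength_nm=463.0, r_mea=1.0, r_A=0.5)
rng = np.random.default_rng(7)

# --- part 1: trace fit ----------------------------------------------------
rate = 2.4  # nm/s
ts = np.arange(0.0, 200.0, 1.0)
true_offset = 390.0  # final thickness when the trace ends
d_true = true_offset + rate * (ts[-1] - ts)
trace = reflectivity(d_true, params) + rng.normal(0, 0.02 * params.r_A, ts.shape)
fit = fit_trace(trace, ts, rate, params, d_offset_search_nm=(300, 500))
print(f"trace fit: offset {fit.offset_nm:.1f} nm (generated with {true_offset:.0f} nm)")
print(f"thickness at the last frame: {fit.d_nm[-1]:.1f} nm")

# --- part 2: per-pixel map refinement ------------------------------------
truth = 188.0 + np.linspace(-10, 10, 64)[None, :] + np.zeros((64, 1))
span = 400.0  # nm of material removed while the series was recorded
stack = reflectivity(truth[None] + np.linspace(0, span, 168)[::-1, None, None], params)
amplitude = stack.max(axis=0) - stack.min(axis=0)
frame = reflectivity(truth, params) + rng.normal(0, amplitude / 20)  # SNR 20
init = ThicknessMap(truth + rng.normal(0, 15, truth.shape), 0.1, method="geometric")

fitted = fit_thickness_map(frame, init, params, norm_min=stack.min(axis=0),
                           norm_max=stack.max(axis=0), norm_span_nm=span)
err = fitted.values_nm - truth
print(f"\nmap fit: mean error {np.nanmean(err):+.1f} nm "
      f"(per-pixel SD {np.nanstd(err):.1f} nm)")
print(f"uniformity sigma: {fitted.metadata['uniformity_sigma_nm']:.1f} nm")
print("The mean map error stays within a few nm even though single pixels")
print("near a fringe extremum are poorly conditioned; the geometric init")
print("confines the fit to the correct interference order.")
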