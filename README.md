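# lamellometer

Thickness and quality control for cryo-FIB lamella fabrication, as a
Python library with a thin command-line interface.

Electron cryotomography needs lamellae — slabs milled out of
frozen-hydrated cells with a focused ion beam — that are 100–200 nm
thick. `lamellometer` implements the calibration-free measurements that
make that thickness controllable *during* milling with a light microscope
coincident with the FIB-SEM, plus the benchmark used to validate them:

| module   | method | idea |
|----------|--------|------|
| `optics` | RIM targeting | a dry objective (n₁ = 1.0) imaging into vitreous ice (n₂ = 1.28) compresses the axial coordinate; the scaling factor S = z_actual/z_nominal places an asymmetric milling pattern that always encloses the fluorescent target |
| `rlm`    | geometric | the foil-side wedge of width w seen in reflected light gives d = w·sin θ for milling angle θ |
| `tfi`    | thin-film interference | reflectivity r(d) = r_mea + r_A·e^(−d/L)·cos(4πd·n₂/λ + π) oscillates with thickness; normalized error minimization refines d to nm scale per pixel |
| `q4stem` | electron scattering | the dark-field/bright-field ratio of the transmitted 30 keV beam grows monotonically with thickness and is inverted against a Monte-Carlo lookup table |
| `eftem`  | zero-loss benchmark | t = λ_inel·ln(I₀/I) with λ_inel ≈ 320 nm at 300 keV, baseline-corrected to zero in vacuum |

`synth` renders every modality from a ground-truth phantom, so the whole
package is testable without microscope data; `mc` is the single-scattering
Monte-Carlo transport (screened-Rutherford elastic scattering, Joy–Luo
continuous slowing-down) behind the q4STEM table and the beam-damage
containment estimate.

## Worked example

```python
import numpy as np
from lamellometer import (AxialScalingModel, focal_shift, thickness_from_wedge,
                          build_table, thickness_from_pattern)
from lamellometer.synth import make_phantom, render_scatter_patterns

# geometric estimate from a measured wedge width
print(thickness_from_wedge(2.5, 10.0))        # 434.1 nm  (w = 2.5 um at 10 deg)

# focal shift for an emitter 9 um deep under the RIM
model = AxialScalingModel(na=0.85, n1=1.0, n2=1.28)
print(round(focal_shift(model, 9.0), 2))      # 2.52 um

# q4STEM: invert a scattering pattern of a 300 nm lamella
table = build_table(np.linspace(50, 1000, 20), n_electrons=20000, seed=1)
phantom = make_phantom(center_thickness_nm=300.0)
patterns, truth = render_scatter_patterns(
    phantom, [(150, 50)], dose=20000, seed=5)
print(round(thickness_from_pattern(patterns[0], table, incidence_deg=0.0)
            .path_length_nm))                 # 297 nm (truth 300, counting noise)
```

The first number is the wedge-geometry thickness of a thinned lamella;
the second is how much deeper a fluorescent target actually sits than the
microscope reports at the deepest linear-regime depth; the third
round-trips a simulated 300 nm lamella through the scattering pipeline.

Longer narrative scripts live in `examples/` (one per capability):

```bash
python examples/rim_targeting.py
python examples/rlm_thickness_monitoring.py
python examples/tfi_thickness_mapping.py
python examples/q4stem_thickness.py
python examples/eftem_benchmark.py
```

## Command line

```bash
lamellometer synth rlm --seed 5 --out demo/           # synthetic milling series
lamellometer rlm-thickness --stack demo/rlm_series.ome.tif --theta 10
lamellometer rim-shift --depth 4.5 --depth 9 --na 0.85
lamellometer q4stem-table --energy 30 --grid 50:1000:20 --n 20000 --seed 1 --out table.csv
```

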