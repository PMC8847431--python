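# hccimg

Multi-modal 3D radionuclide imaging with a ring of hybrid Compton
cameras (HCCs): a list-mode Monte Carlo event generator, the per-mode
event selection, three reconstruction algorithms, and a
photopeak-ratio absorber-thickness estimator.

## The problem

Nuclear-medicine tracers emit photons from tens of keV to several MeV,
but each conventional scanner covers only a slice of that range: SPECT
collimators work at low energy, PET requires positron emitters, and
Compton cameras favour high energy.  A hybrid Compton camera is a
two-plane pixelated scintillator (45×45 GAGG pixels per plane, 40 mm
apart) whose front plane serves simultaneously as

* a **Compton scatterer** for photons above ~200 keV — scatter in the
  front plane plus absorption in the rear plane of the same camera
  constrains the source to a cone through the Compton relation
  `cos θ = 1 − m_e c² (1/E_r − 1/(E_f+E_r))`;
* an **active pinhole shield** for photons below ~200 keV — a central
  3×3 mm² aperture lets photons reach the rear plane only through the
  hole, and any front-plane interaction vetoes the event;

while coincident ~511 keV deposits in *two different* cameras of the
ring define **PET** lines of response.  Four cameras around the source
plus source rotations (12 effective angles by default) give 3D images
in all three modes from a single measurement.  This package is for
anyone who wants to study that imaging chain quantitatively —
selection windows, system models, iteration counts, activity ratios,
absorber effects — without the instrument.

Reconstruction uses list-mode MLEM with the simplified cone system
matrix for Compton mode,

    t_kj = 2π(1 − d/√(d²+a²)) · exp(−((|Θ_j|−|θ_k|)/σ)²/2) / sin θ_k,

hist-mode MLEM with a steric-angle × interaction-probability system
matrix for pinhole mode, and exact-chord back projection of the LORs
for PET.  A spectral module fits 81/356 keV photopeak areas of Ba-133
behind water and inverts the log-linear ratio-vs-thickness calibration
`ln R = ln R₀ − Δμ·d` to estimate absorber thickness.  See
`docs/methods.md` for the model details and numerical choices.

## Worked example

Simulate a Cs-137 point source (904 kBq, 300 s per angle) at
x = z = 20 mm in the 12-angle ring and reconstruct it in Compton mode:

```python
import numpy as np

from hccimg import SourceSpec, VoxelGrid, default_ring
from hccimg import pipeline, postprocess
from hccimg import recon_compton as rc

setup = default_ring()                       # 4 cameras x 3 rotations
source = SourceSpec("cs137", activity_bq=9.04e5, position=(20.0, 0.0, 20.0))

events, emitted = pipeline.simulate_and_select(
    source, setup, mode="compton", target="cs137",
    duration_s=300.0, seed=42,
)
print(f"selected Compton events: {len(events)}")

grid = VoxelGrid.centered(31)                # 31^3 voxels, 2.3 mm pitch
sens = rc.sensitivity_mc(setup, grid, "cs137", n_photons=int(1e8), seed=7)
image = rc.mlem_listmode(events, grid, sens, sigma=np.deg2rad(2.5), n_iter=20)

peak = postprocess.find_peak(image)
print(f"peak voxel {peak.index} at {peak.position_mm} mm")
print(f"FWHM per axis: {np.round(peak.fwhm_mm, 1)} mm")
```

Output:

```
selected Compton events: 4064
peak voxel (24, 15, 24) at [20.7  0.  20.7] mm
FWHM per axis: [7.5 6.6 7.8] mm
```

4064 events pass the Cs-137 hit-pattern and energy cuts (20 < E_f < 80,
607 < E_f+E_r < 717 keV); after 20 MLEM iterations the image maximum
sits at (20.7, 0, 20.7) mm — the voxel containing the true source —
with a point-spread FWHM of 7–8 mm.

The same machinery drives the other modes (`recon_pinhole.mlem_hist`,
`recon_pet.backproject_lors`) and the thickness analysis
(`spectrum.build_calibration` / `estimate_thickness`).  A thin CLI
wraps the library for shell use:

```
hccimg simulate --config cfg.yaml --seed 1 --out events.h5
hccimg recon compton --events events.h5 --target cs137 --iters 20 --out vol.raw
hccimg analyze peak --volume vol.raw
```

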