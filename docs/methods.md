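# Methods

This note documents the physical model, the reconstruction algorithms,
the synthetic-data generator, and the numerical choices made in
`hccimg`.

## The instrument being modelled

A hybrid Compton camera (HCC) is a pair of pixelated Ce:GAGG
scintillator planes: a 45×45 front plane (1×1×3 mm³ pixels) with a
central 3×3 mm² aperture, and a 45×45 rear plane (1×1×5 mm³ pixels)
40 mm behind it.  Four such cameras face a common origin, opposite
front faces 300 mm apart; rotating the sources in steps (30° steps by
default, three rotations → 12 effective view angles) completes the
tomographic acquisition.  One instrument provides three modalities at
once:

* **Compton mode** (high energy, ≳200 keV): a photon scatters in the
  front plane and is absorbed in the rear plane of the same camera.
  The energy pair (E_f, E_r) fixes the scattering angle through the
  Compton relation, so each event constrains the source to a cone.
* **Pinhole mode** (low energy, ≲200 keV): the front plane is opaque
  and acts as an *active* pinhole shield — photons reaching the rear
  plane without a front interaction passed through the aperture.
* **PET mode**: coincident ~511 keV deposits in two different cameras
  define a line of response (LOR) through the annihilation point.

Event selection is hit-pattern based (front&&rear per camera for
Compton; rear-only for pinhole; two cameras for PET), followed by
per-nuclide energy windows.  The Compton front window (20–80 keV)
removes back-scatter orderings.  One list-mode stream feeds all three
selections after the measurement.

## Monte Carlo event generator

Per decay, emission lines fire independently with their tabulated
intensities; directions are isotropic; annihilation pairs are emitted
back to back.  Transport is single-photon and analytic:

* **Water slabs** attenuate with `exp(-μ_w(E)·path)` (narrow-beam).  An
  optional single-scatter mode redirects one Klein–Nishina scatter per
  absorbed photon toward the cameras; it is off by default because no
  quantitative scatter background is being reproduced.
* **Front plane**: a photon either crosses the aperture (tested at the
  entrance face only), interacts with probability
  `1-exp(-μ_GAGG(E)·3mm/cosα)`, or transmits.  Interactions split
  photoelectric/Compton by cross-section fractions; a Compton scatter
  deposits `E-E'` and propagates the scattered photon to the rear
  plane.
* **Rear plane**: interaction probability with the 5 mm path (oblique
  `1/cosα` scaling); photoelectric absorbs fully, otherwise a single
  Compton partial deposit is recorded and the scattered photon escapes.
* **Positions** are entry-pixel centers (no depth of interaction);
  deposits are blurred with the resolution model and time-stamped by a
  Poisson process at the summed activity; hits below a 5 keV trigger
  threshold are dropped.

Attenuation is modelled as analytic Klein–Nishina incoherent scattering
(electron densities: water 0.5551·N_A e⁻/g, GAGG 0.4391·N_A e⁻/g at
6.63 g/cm³) plus a log–log interpolated photoelectric grid digitized
from standard compilations; the GAGG grid resolves the Gd K edge at
50.2 keV.  Coherent scattering, Doppler broadening, intra-plane
multiple interactions, fluorescence escape and the tungsten case
(perfect absorber off the front face) are not modelled.  Emission
cascades are decoupled: true coincidence summing between lines of the
same decay (e.g. In-111 171+245 keV) is absent; random coincidences
between decays are present through the shared time axis.

The energy resolution follows `FWHM%(E) = sqrt(α + β/E)` least-squares
fitted to the measured pixel calibration points (7.3 % at 662 keV,
7.8 % at 511 keV, 22.8 % at 60 keV); the fitted curve passes within the
quoted uncertainties of all three.

**Sampling strategy.** Isotropic emission is implemented by drawing the
per-camera photon counts from a multinomial over the exact solid angles
of spherical caps circumscribing each front face, then sampling
directions uniformly within each cap and applying the exact footprint
test.  This is distribution-identical to brute-force isotropic
emission (the caps are disjoint for every geometry used here; the code
falls back to brute force otherwise) while only tracking photons that
can reach a camera.  Annihilation pairs are traced brute force with a
cap pre-cull applied to both photons.  Emitted-photon bookkeeping
always counts the full isotropic emission.

**A consequence worth knowing**: at pinhole energies, a small-angle
front Compton scatter can deposit less than the trigger threshold, so
the front veto fails and the event is classified rear-only.  These
events form a diffuse, aperture-independent background under the true
pinhole signal (roughly comparable in rate for a 60 keV source).  They
are physical in this model; tests of the pure aperture geometry disable
the threshold to isolate the geometric signal.

## Reconstruction

**Compton (list-mode MLEM).**

    λ_j^n = λ_j^{n-1} Σ_k (1/s_j^{l_k}) · t_kj v_k / (Σ_j' t_kj' λ_j'^{n-1})

with the simplified cone system matrix

    t_kj = 2π(1 - d/√(d²+a²)) · exp(-((|Θ_j|-|θ_k|)/σ)²/2) / sin θ_k

where `a` is the voxel half-pitch, `d` the scatter-pixel→voxel
distance, `Θ_j` the angle between the scatter axis (absorption→scatter)
and the voxel direction, and `θ_k` the kinematic scattering angle.
Both angles are treated as magnitudes in [0, π].  Choices:

* σ = 2.5° default (angular uncertainty; kept small to avoid double
  counting the blur already present in θ_k).
* v_k = 1 for every event; retained as a hook for future weighting.
* Sparsification at the 3σ shell (entries below e^{-4.5} of the ridge
  are dropped); the sparse matrix is assembled row-sorted in one pass.
* λ⁰ = 1 everywhere; events whose truncated row is empty are dropped
  with a warning.
* Iterations: 20 for the tri-modal demonstration, 10 for bottle-style
  runs (convergence-checked defaults).

The per-angle sensitivity s_j^l is estimated by Monte Carlo: a uniform
box source covering the field of view irradiates the cameras at each
angle; accepted-event origins are binned into 5³ coarse cells, divided
by per-cell emissions, smoothed by one 3³ box pass and floored at 1 %
of the map median (prevents division blow-up at the FOV edge).  For
phantom-free acquisitions the per-angle maps are the angle-0 map
evaluated at rotated voxel positions, which is exact for rigid
rotations about the vertical axis.

With few view angles (all in one horizontal plane), cone reprojection
produces streak build-up near the FOV corners; quantitative statements
therefore use ROIs or peaks in the neighbourhood of the sources rather
than the global image maximum when the acquisition has ≤8 angles.

**Pinhole (hist-mode MLEM).**  Detector bins are (angle, camera, rear
pixel); all angles share one image:

    λ_j^n = λ_j^{n-1}/(Σ_i c_ij) · Σ_i c_ij y_i / (Σ_j' c_ij' λ_j'^{n-1})

with `c_ij = Ω_ij · p_int(E)`: the small-angle solid angle of the 1 mm²
rear pixel at the voxel (`A cosα/r²`; relative error < 1e-4 at these
distances) when the pixel→voxel ray passes the aperture (binary test at
the front entrance plane), times the rear-slab interaction probability
`1-exp(-μ_GAGG(E)·5mm/cosα)`.  Voxels whose rays miss every aperture
are excluded from the support; counts in detector bins with an all-zero
system row cannot be modelled and are dropped with a warning (this
preserves exact count conservation over the modelled bins).

**PET.**  Events with exactly two cameras inside the 471–551 keV
per-camera window (three or more qualifying cameras are ambiguous and
discarded) define LORs between the detection pixel centers (front pixel
if the camera saw a front deposit, else rear).  Reconstruction is plain
back projection with exact voxel-chord lengths (Siddon-style
parametric traversal; a point on a voxel boundary belongs to the
lower-index voxel).  No filtering, normalisation or iteration — the
modality is demonstrated at the back-projection level only.

## Photopeak-ratio thickness estimation

Water between source and camera attenuates 81 keV photons faster than
356 keV photons, so the net-area ratio R = A(81)/A(356) of a Ba-133
spectrum decays as `R(d) = R₀ e^{-Δμ·d}` with
Δμ = μ_w(81) − μ_w(356) ≈ 0.063 cm⁻¹ in this attenuation model
(coherent scattering excluded; standard tables including it give
≈ 0.072 cm⁻¹ — the calibration is self-consistent either way because
the same model generates calibration and measurement).  Areas come from
Gaussian + local-linear-background fits with asymmetric windows
(81 keV: −15/+24 keV; 356 keV: −26/+48 keV) chosen to exclude the 53
and 303 keV satellite lines.  Two-pass weighting (second pass weighted
by the fitted model rather than the observed bins) removes the
low-count bias of Poisson-weighted least squares; optionally the peak
width is constrained to ±25 % of the detector resolution model, which
stabilises areas without biasing ratios (the peak shape is
thickness-independent).  `ln R` is fitted against thickness by weighted
least squares; inversion is `d̂ = ln(R₀/R)/Δμ` with errors propagated
from the fit covariance and the measured-ratio error.  Net
(background-subtracted) areas are used; gross counts would change R₀
but not the slope.

## Problem sizes used

Synthetic studies run at reduced scale by shortening the exposure,
never by changing the physics or geometry:

* tri-modal demonstration: paper activity ratios (Cs-137 904 kBq,
  Na-22 45 kBq, Am-241 3.93 MBq), ~200–700 s per angle → roughly
  2×10³–10⁴ Compton, ~5×10³ PET and 10⁵ pinhole events;
* In-111 ratio: 0.27/0.36 MBq sources, 150 s per angle over 8 angles,
  ~1.2×10⁴ Compton events (ratio reproducibility ±0.08 at this size);
* thickness study: 30 min per configuration with a 2.2 MBq source
  (4×10⁹ decays per node), giving ≈0.1 cm statistical accuracy;
* sensitivity maps: 1–3×10⁸ emitted photons per acquisition.

## What passing tests do and do not show

The generator reproduces the geometry, energetics, selection logic and
count statistics of the instrument, so passing tests demonstrate that
the reconstruction chain localises sources, recovers intensity ratios
and inverts the attenuation calibration *under this physics model*.
They do not validate against detector-specific effects absent from the
model: optical light transport, pixel cross-talk, dead time,
fluorescence escape, Doppler broadening, cascade summing and the real
scatter environment.  Absolute efficiencies agree with the instrument
only at the order-of-magnitude level, and the absolute photopeak ratio
R₀ is model-specific (the thickness estimate, a ratio-of-ratios, is
not).

## Known limitations

* Limited-angle cone artifacts near the FOV edge in Compton mode (see
  above); a support mask or more view angles would mitigate them.
* The sensitivity model assumes rotational symmetry when reusing the
  angle-0 map; acquisitions with static phantoms must disable that
  reuse.
* Water-slab attenuation applies only to photons headed to the slab's
  camera, and slabs follow their camera under rotation; a patient-like
  absorber surrounding the source is not modelled.
* Pinhole aperture edges are ideal (no penumbra or septal penetration
  modelling beyond straight-line front-slab transmission).
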