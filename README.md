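# xfct — benchtop pinhole X-ray fluorescence computed tomography

`xfct` simulates and quantitatively reconstructs X-ray fluorescence CT
(XFCT) of gadolinium nanoparticle distributions, for the benchtop scanner
class built from a conventional X-ray tube, a rotation stage, a rectangular
single-pinhole tungsten collimator and a linear photon-counting detector.
It is aimed at people developing or evaluating such systems: it provides a
physics-grounded forward simulator of multi-energy-bin fluorescence
sinograms, the energy-bin Compton-scatter correction, and
attenuation-corrected MLEM reconstruction with a pinhole-response system
matrix, together with the concentration-calibration and detectability
analyses used in phantom studies.

## The method

An incident fan beam (tube spectrum hardened with Cu filtration so that
most photons lie above the Gd K edge at 50.2 keV) excites Gd K-fluorescence
(Kα1 = 42.98, Kα2 = 42.28 keV) in the slice. A photon-counting detector
behind a pinhole records three adjacent energy bins, 33–39 / 39–45 / 45–51
keV; only the middle bin contains fluorescence, all three contain Compton
scatter.

**Scatter correction.** Assuming one representative scatter angle θᵢ per
detector pixel, the theoretical relative number of scattered photons per
bin is r_b(i) = ∫_bin I₀(E) f_KN(E, θᵢ) dE with f_KN the Klein–Nishina
cross-section, and the background under the fluorescence bin is estimated
from the side bins,

    Sca(i) = ( (r_mid/r_low)·Ns_low(i) + (r_mid/r_high)·Ns_high(i) ) / 2,
    N_XRF(i) = Ns_mid(i) − Sca(i).

**Reconstruction.** The Gd image f is reconstructed by MLEM,

    f_j ← f_j / Σᵢ a_ij · Σᵢ a_ij g_i / Σ_j' a_ij' f_j' ,

with the system matrix combining the pinhole solid-angle response Ω and
two-energy attenuation along the entry (incident effective energy) and exit
(Kα1) legs:

    a_ij = Ω_{B→p} · exp(−∫_A^B μ(E_inc, l) dl) · exp(−∫_B^C μ(E_xrf, l) dl).

The attenuation maps come from a transmission-CT slice (filtered
backprojection) decomposed into three materials — NaGdF4, bone, water —
with the Gd term taken from a first, attenuation-free reconstruction pass.
ROI means over insertions of known concentration calibrate the image to
mg/mL; contrast-to-noise ratios and the Rose criterion (CNR > 4) give the
detectability limit.

## Worked example

Closed loop on the digital six-insertion PMMA calibration phantom
(128 × 128 grid at 0.5 mm, 45 views, Poisson noise, 100 MLEM iterations):

```python
import numpy as np
from xfct import physics
from xfct.forward import AcquisitionProtocol, simulate_transmission, simulate_xfct
from xfct.geometry import SystemGeometry, VoxelGrid
from xfct.metrics import fit_calibration, roi_stats
from xfct.phantom import calibration_phantom, rasterize
from xfct.recon import fbp_slice, reconstruct_quantitative

grid = VoxelGrid(128, 128, 0.5)            # 64 mm field, 0.5 mm voxels
geom = SystemGeometry()                    # 75 / 63.5 mm pinhole bench
spectrum = physics.IncidentSpectrum.filtered_tube(140, 0.4)
ct_spectrum = physics.IncidentSpectrum.filtered_tube(65, 0.1)

spec = calibration_phantom()               # six insertions, 0-20 mg/mL Gd
truth = rasterize(spec, grid)
protocol = AcquisitionProtocol(n_views=45, source_fluence=1e9)

sinos = simulate_xfct(truth, geom, spectrum, protocol, seed=1)
trans = simulate_transmission(truth, ct_spectrum, seed=2)
mu_ct = fbp_slice(trans)
result = reconstruct_quantitative(sinos, mu_ct, trans.energy_keV,
                                  spectrum, grid, n_iter=100,
                                  stop_rel_change=None)

concs = [i.concentration for i in spec.insertions]
means = [roi_stats(result.image.values, grid, i.center, 0.7 * i.radius)[0]
         for i in spec.insertions]
fit = fit_calibration(means, concs)
recovered = (np.asarray(means) - fit.intercept) / fit.slope
for c, r in zip(concs, recovered):
    print(f"true {c:5.1f} mg/mL  ->  recovered {r:6.2f} mg/mL")
print(f"calibration r-square = {fit.r_square:.4f}")
```

prints

```
true   0.0 mg/mL  ->  recovered   0.04 mg/mL
true   2.0 mg/mL  ->  recovered   2.02 mg/mL
true   5.0 mg/mL  ->  recovered   5.00 mg/mL
true  10.0 mg/mL  ->  recovered   9.89 mg/mL
true  15.0 mg/mL  ->  recovered  15.00 mg/mL
true  20.0 mg/mL  ->  recovered  20.05 mg/mL
calibration r-square = 0.9999
```

i.e. after scatter and attenuation correction the reconstructed pixel value
is linear in the true Gd concentration over the full 0–20 mg/mL range, and
the calibration line inverts it to within a few percent per insertion.

The same pipeline is available from the shell, driven by a YAML
configuration:

```bash
xfct pipeline --config run.yaml --seed 1 --out runs/demo
```

which writes the sinograms, CT and XFCT images (TIFF + JSON sidecars), a
calibration/CNR report and a run manifest, and can be resumed stage by
stage (`xfct simulate | correct | recon-ct | recon-xfct | calibrate`).

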