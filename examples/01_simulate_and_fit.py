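"""Simulate one bacterium with a free cytoplasmic protein and fit its
displacement distribution.

A spherocylindrical cell (2.02 um x 0.32 um radius) holds 60 molecules
diffusing at D = 5 um^2/s. Stroboscopic frame pairs with a 1.5 ms
peak-to-peak interval sample each molecule's displacement; pairing within
r_max = 600 nm plus a background term handles false matches.
"""

import numpy as np

from smdmap import (AcquisitionSpec, PopulationSpec, Spherocylinder,
                    closed_form_diffusion, extract_displacements,
                    fit_displacement_mle, simulate_dataset)

cell = Spherocylinder(length_total_nm=2020.0, radius_nm=320.0,
                      center_nm=(5000.0, 5000.0), axis_angle_deg=15.0)
populations = [PopulationSpec("cytoplasm_3d", D_true=5.0, fraction=1.0,
                              n_molecules=60)]
acq = AcquisitionSpec(dt_peak_to_peak_ms=1.5, n_frame_pairs=6000,
                      loc_sigma_nm=20.0, detection_prob=0.01,
                      background_rate=0.002, rng_seed=1, fov_nm=10_000.0)

table, truth = simulate_dataset([cell], populations, acq)
ds = extract_displacements(table, dt_ms=1.5, r_max_nm=600.0)
fit = fit_displacement_mle(ds, n_components=1)

print(f"localizations: {len(table)}, displacements: {len(ds)}")
print(f"fitted D  = {fit.components[0][0]:.2f} um^2/s "
      f"(true 5.0; background slope b = {fit.b:.2e} /nm^2)")
print(f"moment D  = {closed_form_diffusion(ds):.2f} um^2/s "
      "(mean r^2 / 4 dt, no background correction)")
print("The fitted D is the apparent in-plane diffusion coefficient; it")
print("includes the localization error and cell-confinement offsets that")
print("the displacement model does not correct for.")
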