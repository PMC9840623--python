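"""End-to-end run: simulate a field of cells, then segment, fit and map.

The pipeline clusters the point cloud into cells, aligns each cell, fits
the whole cell and its pole/middle regions with the background-corrected
displacement model, and reconstructs the 50 nm diffusivity map, emitting a
machine-readable report.
"""

import json

from smdmap import (AcquisitionSpec, PopulationSpec, RunConfig,
                    Spherocylinder, run_smdm_pipeline, simulate_dataset)

cells = [Spherocylinder(2020.0, 320.0, (4000.0 + 4000.0 * i, 12_500.0),
                        axis_angle_deg=20.0 * i - 40.0) for i in range(5)]
populations = [PopulationSpec("cytoplasm_3d", D_true=5.0, fraction=1.0,
                              n_molecules=60)]
acq = AcquisitionSpec(dt_peak_to_peak_ms=1.5, n_frame_pairs=2500,
                      loc_sigma_nm=20.0, detection_prob=0.008,
                      background_rate=0.002, rng_seed=11)

table, _ = simulate_dataset(cells, populations, acq)
report = run_smdm_pipeline(table, RunConfig(), out_dir="scratch/pipeline_demo")

print(f"localizations: {report['n_localizations']}, "
      f"cells accepted: {len(report['cells'])}, "
      f"rejected clusters: {len(report['rejected_clusters'])}")
for c in report["cells"]:
    whole = c["fits"]["whole"]
    print(f"cell {c['cell_id']}: {c['n_displacements']} displacements, "
          f"D = {whole['D'][0]:.2f} um^2/s, "
          f"map valid pixels = {c['map']['n_valid_pixels']}")
print("Every input row is accounted for:", json.dumps(report["accounting"]))
print("Per-cell D values scatter a few percent around the true 5 um^2/s.")
print("At ~1500 displacements per cell every 50 nm map pixel stays below")
print("the 20-displacement minimum and is masked; diffusivity maps need")
print("~10x longer acquisitions (see example 04 for a well-sampled map).")
print("Maps, aligned tables and the JSON report are in scratch/pipeline_demo.")
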