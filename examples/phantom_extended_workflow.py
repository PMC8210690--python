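"""Run the continuous dye-front workflow on a synthetic tubule.

Renders a straight proximal-tubule phantom filling at a known flow of
1.7 nl/min, then runs the full estimator: bleedthrough cleanup, 3D watershed
segmentation, kymograph construction, turning-point thresholding and
volume-vs-time regression.
"""

from sngfr import analyze_extended, default_spec, render_phantom

spec = default_spec(flow_nl_min=1.7, noise_sigma=0.05, seed=42)
series, volumes, roi, truth = render_phantom(spec)
row = analyze_extended(series, volumes, roi, dataset_id="phantom-42")

print(f"ground-truth flow     : {truth.q_nl_min:.3f} nl/min")
print(f"estimated snGFR       : {row.sngfr_nl_min:.3f} nl/min")
print(f"regression R²         : {row.r_squared:.4f}")
print(f"tubule length (ROI)   : {row.pt_length_um:.1f} µm")
print(f"segmented PT volume   : {row.pt_volume_um3:.0f} µm³")
print(f"front threshold       : {row.threshold:.1f} (intensity units)")
print(f"frames in regression  : {row.n_frames_used}")
# The estimate should sit within a few percent of the ground truth: the
# regression slope (µm³/frame) times the frame rate, converted to nl/min,
# recovers the volumetric inflow that drives the dye front.
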