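"""Repeatability contrast: continuous workflow vs the legacy two-point method.

One phantom is rendered once; twenty replicates re-annotate it with jittered
ROI vertices and jittered manual diameters, emulating repeated manual
analysis of the same acquisition. The continuous estimator needs no manual
diameters and integrates the whole transit, so its replicate spread (CV)
should be much smaller than the two-point method's.
"""

from sngfr import default_spec, jitter_study

res = jitter_study(
    default_spec(flow_nl_min=1.7, noise_sigma=0.0, seed=0),
    n_replicates=20,
    roi_jitter_px=1.0,
    diameter_jitter_frac=0.05,
    base_seed=1,
)

print(f"true flow                    : {res['q_true_nl_min']:.2f} nl/min")
print(f"continuous: mean ± CV        : {res['extended'].mean():.3f} nl/min, "
      f"CV {res['cv_extended_percent']:.2f}%")
print(f"two-point : mean ± CV        : {res['twopoint'].mean():.3f} nl/min, "
      f"CV {res['cv_twopoint_percent']:.2f}%")
# The CV ratio quantifies how much of the two-point method's variance comes
# from the manual inputs (diameters enter squared) that the continuous
# workflow eliminates.
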