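"""Extract blood-pool curves from a 2D+t perfusion stack and measure PTT.

Emulates the clinical workflow: a perfusion image series plus RV/LV ROI
masks, per-frame ROI averaging into time–signal curves, then peak-to-peak
transit-time estimation.
"""

from pttkit import (
    BolusParams,
    compute_ptt,
    extract_time_signal_curve,
    simulate_perfusion_stack,
)

series, rv_mask, lv_mask, truth = simulate_perfusion_stack(
    BolusParams(transport_delay=7.0, noise_sd=2.0, seed=7), shape=(32, 32)
)
print(f"stack: {series.voxels.shape[0]}x{series.voxels.shape[1]} voxels, "
      f"{series.n_frames} frames, RV ROI {rv_mask.n_voxels} voxels, "
      f"LV ROI {lv_mask.n_voxels} voxels")

rv = extract_time_signal_curve(series, rv_mask)
lv = extract_time_signal_curve(series, lv_mask)
m = compute_ptt(rv, lv)

print(f"true transit time : {truth['ptt_true']:.3f} s")
print(f"estimated PTT     : {m.ptt_s:.3f} s  (nPTT {m.nptt:.3f})")
# ROI averaging over many voxels suppresses per-voxel noise, which is why the
# extracted-curve estimate is close to the truth despite noisy voxels.
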