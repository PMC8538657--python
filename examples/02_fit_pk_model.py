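"""Fit the two-compartment filtration model and compute single-kidney GFR.

A noiseless phantom provides a mean cortical signal curve with known
ground truth; the curve is inverted to concentration through the SPGR
signal equation and fitted by bounded trust-region least squares.
"""

from renodce import pk
from renodce.phantom import PhantomConfig, make_phantom

phantom = make_phantom(PhantomConfig(shape=(192, 192, 6), noise_sigma=0.0, seed=2))

curve = pk.mean_cortex_curve(phantom.series, phantom.labels)
conc = pk.signal_to_concentration(
    curve,
    phantom.series.frame_times,
    phantom.series.n_baseline_frames,
    t10_s=phantom.config.t10_s["cortex"],
    r1=phantom.config.r1,
    tr_ms=phantom.series.tr_ms,
    flip_angle_deg=phantom.series.flip_angle_deg,
)
fit = pk.fit_2cfm(conc, phantom.aif, n_baseline=phantom.series.n_baseline_frames)
gfr = pk.compute_gfr(fit.params.ktrans_per_min, phantom.labels,
                     phantom.series.voxel_volume_ml)

true = phantom.true_params["cortex"]
print("fitted vs true 2CFM parameters:")
print(f"  Ktrans [1/min]: {fit.params.ktrans_per_min:.4f}  (true {true.ktrans_per_min})")
print(f"  vp     [-]    : {fit.params.vp:.4f}  (true {true.vp})")
print(f"  delay  [s]    : {fit.params.delay_s:.4f}  (true {true.delay_s})")
print(f"  Tg     [s]    : {fit.params.tg_s:.4f}  (true {true.tg_s})")
print(f"residual sum of squares: {fit.rss:.3e}")
print(f"SK-GFR (both kidneys' cortex): {gfr.gfr_ml_min:.2f} mL/min "
      f"= Ktrans x {gfr.cortex_volume_ml:.1f} mL cortex")
# On noiseless input all four parameters are recovered to well under 1%,
# so the GFR error is dominated by segmentation, not fitting.
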