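"""Quantify recruitment kinetics at a laser-microirradiation stripe.

Simulates 10 cells imaged for 80 frames at 15 s intervals with damage after
frame 5 (6.5 x 1 µm stripe), recruitment amplitude A = 0.8 and tau = 120 s at
SNR 10 with photobleaching, then extracts damage/control ROI traces, applies
the double normalization R(t) = [F(t)/F(-)]_damage / [F(t)/F(-)]_control,
aggregates across cells, classifies recruitment, and fits the kinetic model
R(t) = 1 + A(1 - exp(-(t - t_dmg)/tau)).
"""

import focikit as fk

kinetics = fk.KineticsSpec(amplitude=0.8, tau=120.0, bleach_rate=0.001)

traces = []
for i in range(10):
    scene = fk.default_stripe_scene(seed=100 + i, snr=10.0)
    movie, truth = fk.generate_stripe_movie(kinetics, scene)
    nucleus_id = int(truth.nucleus_masks[truth.damage_roi.slices].max())
    pair = fk.auto_place_control(
        truth.nucleus_masks == nucleus_id, truth.damage_roi, nucleus_id=nucleus_id
    )
    traces.append(fk.normalize_trace(fk.extract_traces(movie, pair)))

aggregate = fk.aggregate_curves(traces)
label = fk.classify_recruitment(aggregate)
fit = fk.fit_kinetics(aggregate)

plateau = aggregate.mean_ratio[-10:].mean()
print(f"n cells                  : {aggregate.n}")
print(f"plateau (last 10 frames) : {plateau:.3f} +/- {aggregate.sem[-10:].mean():.3f} (model: 1.8)")
print(f"classification           : {label}")
print(f"fitted A                 : {fit.amplitude:.3f} (true 0.800)")
print(f"fitted tau               : {fit.tau:.1f} s (true 120.0 s)")
# Active recruitment means the double-normalized damage/control ratio exceeds
# 1; the double ratio cancels the simulated photobleaching, so the fitted
# (A, tau) recover the generative parameters.
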