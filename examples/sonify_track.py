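"""Map a session's movement onto a music track, offline.

A synthetic two-tone stereo 'track' stands in for the music; the spine channel
degrades it by sample-and-hold decimation, the barbell channel crossfades
between the frontal downmix and the full stereo image.
"""

import numpy as np

from sonolift import kinematics, sonification, synthetic

cfg = synthetic.SimulationConfig(n_reps=4, spine_fault_amplitude=0.6,
                                 barbell_drift=0.1, marker_noise_sd=0.5, seed=7)
capture, truth = synthetic.simulate_session(cfg)
d = kinematics.derive_series(capture, synthetic.DEFAULT_ROLES, truth.profile,
                             truth.rearward_axis)
controls = sonification.build_control_series(d)
print(f"controls: quality range [{controls.quality.min():.3f}, "
      f"{controls.quality.max():.3f}], gain_front range "
      f"[{controls.gain_front.min():.3f}, {controls.gain_front.max():.3f}]")

sr = 22050
t = np.arange(int(capture.duration * sr)) / sr
track = np.column_stack([0.4 * np.sin(2 * np.pi * 220 * t),
                         0.4 * np.sin(2 * np.pi * 277.18 * t)]).astype(np.float32)

for mode in ("spine", "barbell", "combination"):
    rendered = sonification.render_feedback(track, sr, controls, mode)
    side_in = np.sqrt(np.mean(((track[:, 0] - track[:, 1]) / 2) ** 2))
    side_out = np.sqrt(np.mean(((rendered[:, 0] - rendered[:, 1]) / 2) ** 2))
    hf = np.sqrt(np.mean(np.diff(rendered, axis=0) ** 2))
    print(f"{mode:12s}: residual stereo width {side_out / side_in:5.1%}, "
          f"sample-to-sample RMS {hf:.4f}")
print("(spine degradation flattens consecutive samples; barbell drift toward "
      "the toes collapses the stereo width)")

sonification.write_wav("/tmp/feedback.wav", sr, rendered)
print("combination render written to /tmp/feedback.wav")
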