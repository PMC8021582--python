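"""Score video frames for regularity and detect irregular motion.

A small spatiotemporal autoencoder is trained on the regular part of a frame
sequence; per-frame reconstruction errors (all pixel errors summed) are
min-max normalized into an abnormality score a(t) and regularity score
s(t) = 1 - a(t). Irregular motion reconstructs poorly, so s(t) collapses.
"""

import numpy as np

from ictaldetect import (
    AutoencoderConfig,
    frame_errors,
    frames_from_array,
    regularity_score,
    train_autoencoder,
)

rng = np.random.default_rng(0)
# a static scene (sleeping patient) with an injected segment of erratic motion
frames = np.tile(rng.random((16, 16)) * 0.5 + 0.25, (300, 1, 1))
frames += rng.normal(0, 0.01, frames.shape)
frames[180:220] = rng.random((40, 16, 16))

cfg = AutoencoderConfig(temporal_depth=5, input_size=(16, 16),
                        hidden=(64, 16), epochs=30, seed=0)
model = train_autoencoder(frames_from_array(frames[:150], fps=30.0), cfg)

e_t = frame_errors(model, frames_from_array(frames, fps=30.0))
scores = regularity_score(e_t, fps=30.0)
print(f"training loss {model.loss_history[0]:.3f} -> {model.loss_history[-1]:.5f}")
print(f"regularity s(t): outside the segment min {scores.s_t[:170].min():.3f}, "
      f"inside it min {scores.s_t[185:215].min():.3f}")
# s(t) near 1 = familiar, regular motion; the injected segment drives it
# toward 0. This trace then feeds the same forecasting/thresholding path as
# an SEEG channel.
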