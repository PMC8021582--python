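"""Generate a synthetic SEEG channel with ground-truth seizures and save it.

The generator superimposes rhythmic 4 Hz spike-wave events (with amplitude
buildup and cycle-to-cycle jitter) on an oscillatory background whose noise
floor wanders the way real epilepsy-monitoring-unit recordings do.
"""

import numpy as np

from ictaldetect import (
    BackgroundSpec,
    SeizureSpec,
    gen_seeg_channel,
    write_intervals,
    write_recording,
)

background = BackgroundSpec(fs=256.0, duration_s=300.0)
seizures = SeizureSpec(n_events=2, amplitude_gain=5.0, min_gap_s=30.0,
                       event_region=(0.3, 0.95))
series, labels = gen_seeg_channel(background, seizures, seed=7,
                                  patient_id="sim-p0", channel_id="ch0")

write_recording("sim_recording.edf", [series])
write_intervals("sim_events.tsv", labels)

print(f"channel: {len(series)} samples at {series.fs:g} Hz "
      f"({series.duration_s:.0f} s), RMS {np.sqrt(np.mean(series.values**2)):.2f}")
for s, e in labels.intervals:
    ev = series.values[s:e]
    print(f"  event [{s}, {e})  = {s/series.fs:6.1f}-{e/series.fs:6.1f} s, "
          f"RMS {np.sqrt(np.mean(ev**2)):.2f}")
# Event RMS is several times the background RMS: these are the anomalies the
# self-supervised detector must recover without ever seeing a label.
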