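"""Probe patient-specificity: apply one patient's model to another patient.

Models are trained per patient. Applying a model to a recording from a
different spectral family leaves that family's rhythm bursts unexplained,
so false-positive detections rise — the signature of patient-specific
representations.
"""

from ictaldetect import default_families, gen_patient_family, score, SeizureSpec
from ictaldetect.detect import detect_on_series
from ictaldetect.pipeline import PipelineConfig, preprocess_channel
from ictaldetect.threshold import DynamicConfig

fam_a, fam_b = default_families()
pat_a = gen_patient_family(fam_a, 1, seed=0, seizures=SeizureSpec(n_events=2))[0]
pat_b = gen_patient_family(fam_b, 1, seed=1, seizures=SeizureSpec(n_events=2))[0]

cfg = PipelineConfig(threshold=DynamicConfig(window_size=32768, step=16384))
rows = []
for name, model_patient in (("own model", pat_b), ("foreign model", pat_a)):
    fp = tp = 0
    for ch_b, ch_m in zip(pat_b["channels"], model_patient["channels"]):
        donor = detect_on_series(preprocess_channel(ch_m, cfg), forecaster="ar",
                                 split=cfg.split, dynamic=cfg.threshold)
        res = detect_on_series(preprocess_channel(ch_b, cfg), model=donor.model,
                               split=cfg.split, dynamic=cfg.threshold)
        rep = score(res.intervals, pat_b["labels"])
        fp += rep.fp_pred
        tp += rep.tp_pred
    print(f"{name}: {tp} true-positive, {fp} false-positive intervals "
          f"on patient {pat_b['patient_id']}")
# A model carries its training patient's spectral signature: the foreign
# model mispredicts the unfamiliar rhythms and floods the detector.
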