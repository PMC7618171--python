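"""Clinical scoring: PIPP-R, the tachycardia rule and STAI-State totals.

Builds a handful of observations by hand and prints what the rubric and
rules return for them.
"""

import numpy as np

from painrct.scores import (
    STAI_REVERSE_ITEMS,
    PippRObservation,
    detect_tachycardia,
    pipp_r,
    stai_state_score,
)
from painrct.synthetic import VitalTrace

# --- PIPP-R: a moderate pain response in a term baby ----------------------
obs = PippRObservation(
    gestational_age=39.0,
    behavioural_state="quiet_awake",
    baseline_hr=128.0,
    max_hr_post=148.0,        # +20 bpm -> band 2
    baseline_spo2=98.0,
    min_spo2_post=95.0,       # -3 % -> band 1
    brow_bulge_duration=14.0,  # 47 % of the window -> band 2
    eye_squeeze_duration=8.0,  # 27 % -> band 1
    nasolabial_furrow_duration=2.0,  # 7 % -> band 0
)
score = pipp_r(obs)
print("PIPP-R subscores:", score.subscores)
print("PIPP-R total    :", score.total, "(0-21; 7-12 is moderate pain)")

# --- tachycardia: quiet baseline, post-lance surge through 160 bpm --------
t = np.arange(-20.0, 41.0)
hr = np.where(t < 0, 150.0, 166.0)
trace = VitalTrace(time=t + 60.0, heart_rate=hr, spo2=np.full(t.size, 97.0),
                   lance_time=60.0, sham_time=30.0)
print("tachycardia     :", detect_tachycardia(trace))

# --- STAI-State: a mid-anxiety sheet --------------------------------------
items = np.array([2] * 20)
print("STAI-S total    :", stai_state_score(items), "(20-80; ~35 in working adults)")
print("reverse-keyed   :", sorted(STAI_REVERSE_ITEMS))
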