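"""Template-regression scoring of simulated EEG epochs.

Simulates stimulus-locked epochs containing the calibrated biphasic
response template at known magnitudes in 1/f background noise, then
recovers each magnitude as the no-intercept regression coefficient of
the template on the Cz analysis window (400-700 ms post-stimulus).
"""

import numpy as np

from painrct.config import EEGSimConfig
from painrct.nnrf import AlignConfig, build_template, nnrf_magnitude, preprocess, preprocess_template
from painrct.synthetic import simulate_epoch

template = build_template()
filtered_template = preprocess_template(template)  # matched regressor
cfg = EEGSimConfig(latency_jitter_sd_ms=0.0)
rng = np.random.default_rng(0)

for true_magnitude in (0.0, 0.642, 1.07):
    scores = []
    for _ in range(200):
        epoch = preprocess(simulate_epoch(None, true_magnitude, cfg, rng, template))
        res = nnrf_magnitude(epoch, filtered_template, AlignConfig(max_shift_ms=0.0),
                             check_artefact=False)
        scores.append(res.magnitude)
    scores = np.asarray(scores)
    print(
        f"true magnitude {true_magnitude:5.3f} -> recovered "
        f"{scores.mean():6.3f} +/- {scores.std(ddof=1) / np.sqrt(scores.size):.3f} (SE)"
    )
# A magnitude of 1 is calibrated to the expected term-neonate response
# to a heel lance; the scorer is an unbiased projection, so each mean
# sits within sampling error of the planted value.
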