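"""ITT and CACE estimation on a synthetic trial with non-compliance.

Generates a 112-neonate trial in which compliant intervention babies
have their true response magnitude reduced by 40% (a -0.428 a.u.
complier effect) and ~11% of intervention parents stroke too early
(non-compliant). The ITT estimate is attenuated toward zero by the
compliance rate; two-stage least squares with allocation as the
instrument recovers the complier effect.
"""

import dataclasses

from painrct.config import TrialConfig
from painrct.inference import AnalysisSpec, cace_estimate, itt_estimate
from painrct.synthetic import expected_compliance_rate, generate_outcome_frame

cfg = TrialConfig(seed=42, n=112)
cfg = cfg.replace(
    ground_truth=dataclasses.replace(cfg.ground_truth, complier_effect_r=0.4)
)
frame = generate_outcome_frame(cfg)
spec = AnalysisSpec(outcome="nnrf")

itt = itt_estimate(frame, spec)
cace = cace_estimate(frame, spec)
rate = expected_compliance_rate(cfg.compliance)

print(f"expected compliance rate : {rate:.3f}")
print(f"true complier effect     : {-0.4 * 1.07:.3f} a.u.")
print(
    f"ITT  estimate : {itt.estimate:6.3f} "
    f"(95% CI {itt.ci_low:.3f} to {itt.ci_high:.3f}, n={itt.n_analysed})"
)
print(
    f"CACE estimate : {cace.estimate:6.3f} "
    f"(95% CI {cace.ci_low:.3f} to {cace.ci_high:.3f}, n={cace.n_analysed})"
)
# In a single replicate both estimates carry sampling noise of ~0.13 SE;
# over many replicates the ITT mean converges to compliance x CACE.
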