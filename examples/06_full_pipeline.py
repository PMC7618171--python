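"""End-to-end run: simulate -> score -> analyse -> report.

Generates a small trial with raw signals (EEG epochs, vital-sign traces,
facial annotations, STAI sheets), scores every outcome, estimates ITT
and CACE effects with permutation p-values (Holm-adjusted across the
secondary family), and prints the results table plus the sham-validation
check (lance responses must exceed sham responses).
"""

import dataclasses

from painrct.config import TrialConfig
from painrct.pipeline import run_pipeline

cfg = TrialConfig(seed=11, n=24)
cfg = cfg.replace(inference=dataclasses.replace(cfg.inference, n_permutations=200))

report = run_pipeline(cfg)
print(report.to_frame().to_string(index=False))
print()
for name, v in report.sham_validation.items():
    print(
        f"sham validation [{name}]: lance {v['mean_lance']:.2f} vs sham "
        f"{v['mean_sham']:.2f}, paired p = {v['p']:.2g} (n={v['n']})"
    )
print(f"\nprovenance: seed={report.provenance['seed']}, "
      f"config hash {report.provenance['config_hash'][:12]}...")
# Sham epochs contain no planted response, so the lance-sham difference
# is positive by construction; in a null-effect run the arm contrasts
# themselves stay non-significant.
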