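"""Channel-reduction and region-removal ablations.

Runs the two robustness protocols on a small synthetic cohort: uniform
thinning of the montage to fewer channels, and removal of whole scalp
regions with the accuracy drop against the unablated baseline. The second
cohort plants all subject-specific coupling in the frontal channels, so
frontal removal should produce by far the largest drop.
"""

from vnfc import TrainConfig, simulate_cohort
from vnfc.experiments import (
    report,
    run_channel_reduction,
    run_region_removal,
    windows_from_cohort,
)
from vnfc.synthetic import simulate_planted_cohort

cfg = TrainConfig(epochs=20, seed=0)

cohort = simulate_cohort(n_subjects=5, runs_per_subject=2, duration_s=20.0, seed=3)
wc = windows_from_cohort(cohort)
table = run_channel_reduction(wc, model_names=("vn_gcn",), ks=(56, 32, 16), cfg=cfg, seed=3)
print("accuracy vs channel count (fewer channels -> less connectivity detail):")
print(report(table))

planted = simulate_planted_cohort(region="frontal", seed=1)
wcp = windows_from_cohort(planted)
table = run_region_removal(wcp, model_names=("vn_gcn",), cfg=cfg, seed=1)
print("region removal on a frontal-planted cohort "
      "(the frontal row should show the largest drop):")
print(report(table))
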