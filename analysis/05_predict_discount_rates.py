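#!/usr/bin/env python
"""Out-of-sample prediction of log k from DCM parameters.

Leave-one-subject-out elastic net (alpha = 0.3, penalty by inner
cross-validation) on the per-run DCM parameters, with the parameter-
group ablations.  Writes results/predict.json.
"""

from pathlib import Path

from tdconnect.cli import _get_cohort, run_dcm, run_predict
from tdconnect.config import PipelineConfig

OUT = Path("results")

if __name__ == "__main__":
    cfg = PipelineConfig(seed=0)
    cohort = _get_cohort(cfg, OUT)
    posts = run_dcm(cfg, OUT, cohort)
    res, ablations = run_predict(cfg, OUT, cohort, posts)
    cm = res.confusion
    print(f"balanced accuracy: {100 * res.balanced_accuracy:.1f}% "
          f"(95% interval {100 * res.interval_95[0]:.0f}-{100 * res.interval_95[1]:.0f}%)")
    print(f"confusion (TP FN TN FP): {cm.tp} {cm.fn} {cm.tn} {cm.fp}")
    print(f"rank correlation: rho = {res.spearman_rho:.2f}, p = {res.spearman_p:.3g}")
    for name, abl in ablations.items():
        print(f"ablate {name}: MBA = {100 * abl.balanced_accuracy:.1f}%, "
              f"rho = {abl.spearman_rho:.2f}")
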