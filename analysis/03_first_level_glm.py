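#!/usr/bin/env python
"""First-level value GLMs and the full-versus-reduced comparison.

Builds rdSV + Accept designs per run, fits both regions' series with
AR(1) correction, reports the group-level contrasts (the Accept
contrast should localize to dlPFC, the value contrast to vmPFC), and
compares the value model against its reduction by random-effects
Bayesian model selection.  Writes results/glm.json.
"""

from pathlib import Path

from tdconnect.cli import _get_cohort, run_glm
from tdconnect.config import PipelineConfig

OUT = Path("results")

if __name__ == "__main__":
    cfg = PipelineConfig(seed=0)
    cohort = _get_cohort(cfg, OUT)
    res = run_glm(cfg, OUT, cohort)
    for key in ("group_d_accept", "group_v_accept", "group_d_value", "group_v_value"):
        row = res[key]
        print(f"{key}: t = {row['t']:.2f}, p = {row['p']:.2g} (n = {row['n']})")
    print(f"exceedance that the value model beats its reduction: "
          f"{res['value_model_exceedance_full']:.3f}")
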