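#!/usr/bin/env python
"""Attrition analysis: is data-missingness genetically associated with the
exposure score?

Relates the cohort's missingness indicator to the polygenic score by
logistic regression and, at the summary level, regresses per-variant
missingness log odds ratios on exposure and confounder effects (the same
MVR machinery as for the outcomes).  Writes results/attrition.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

import numpy as np
from common import RESULTS, get_study, study_config
from polylink.pipeline import RunConfig, run_pipeline_on_study


def main() -> None:
    study = get_study()
    cfg = study_config()
    report = run_pipeline_on_study(study, RunConfig(sim=cfg, seed=cfg.seed))
    att = report.attrition
    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "attrition.json", "w") as fh:
        json.dump(att, fh, indent=2)

    true_slope = study.config.missingness_slope
    print(f"missing fraction: {att['missing_fraction']:.1%} "
          f"(generating missingness slope {true_slope} log-odds per "
          f"liability-score SD)")
    print(f"PGS association: {att['pgs_logodds_per_sd']:.3f} log-odds of "
          f"missingness per SD of exposure score "
          f"(SE {att['pgs_se']:.3f}, P = {att['pgs_p']:.2g})")
    if "mvr_beta_exposure" in att:
        print(f"summary-level MVR: conditional exposure slope on "
              f"missingness {att['mvr_beta_exposure']:.3f} "
              f"(SE {att['mvr_se_exposure']:.3f}, "
              f"P = {att['mvr_p_exposure']:.2g})")
    direction = "selective dropout of genetically higher-risk children" \
        if att["pgs_logodds_per_sd"] > 0 else "no selective dropout signal"
    print(f"interpretation: {direction}")
    print(f"report written to {RESULTS / 'attrition.json'}")


if __name__ == "__main__":
    main()
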