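#!/usr/bin/env python
"""Polygenic scoring of the cohort: score-outcome associations across
P-value thresholds, with and without diagnosed children.

Builds risk-oriented, clumped scores from the exposure GWAS, regresses
every prepared (covariate-adjusted, rank-transformed) outcome on the
standardized score, and flags associations passing the experiment-wide
threshold.  Writes results/pgs_associations.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd
from common import RESULTS, get_study
from polylink.instruments import LdReference, select_instruments
from polylink.pgs import PGS_THRESHOLDS, compute_pgs, pgs_association
from polylink.pipeline import prepare_phenotypes
from polylink.sumstats import SumstatTable, orient_to_risk
from polylink.transforms import effective_tests, experimentwide_alpha


def main() -> None:
    study = get_study()
    cohort = study.cohort
    prepared = prepare_phenotypes(cohort)
    m_eff, _ = effective_tests(prepared.corr().to_numpy())
    _, alpha = experimentwide_alpha(0.05, round(m_eff))
    print(f"effective number of outcome measures: {m_eff:.1f} -> "
          f"experiment-wide alpha {alpha:.4f}")

    ld = LdReference(study.ld_reference,
                     list(study.genome.variants["variant_id"]))
    oriented = orient_to_risk(study.exposure)
    rows = []
    for thr in PGS_THRESHOLDS:
        scoring = select_instruments(oriented, ld, p_max=thr, label="pgs")
        if len(scoring) == 0:
            continue
        pgs = compute_pgs(cohort.dosages, cohort.variants,
                          SumstatTable("s", "binary", scoring.variants),
                          p_threshold=thr)
        for col in prepared.columns:
            for mask, label in ((None, "all"),
                                (cohort.diagnosed, "excl_diagnosed")):
                r = pgs_association(prepared[col].to_numpy(), pgs,
                                    exclusion_mask=mask, outcome_label=col,
                                    p_threshold=thr)
                rows.append({"outcome": col, "p_threshold": thr,
                             "sample": label, "beta": r.beta, "se": r.se,
                             "p": r.pvalue, "r2_percent": 100 * r.r2,
                             "n": r.n, "pass_experimentwide": r.pvalue < alpha})
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "pgs_associations.tsv", sep="\t", index=False,
                 float_format="%.6g")

    shown = table.query("p_threshold == 0.1 and sample == 'all'")
    print(f"\nat the presented threshold P < 0.1 "
          f"({len(shown)} outcomes):")
    print(f"  inverse associations: {(shown['beta'] < 0).sum()}/{len(shown)}")
    print(f"  variance explained: {shown['r2_percent'].min():.2f}% - "
          f"{shown['r2_percent'].max():.2f}%")
    print(f"  passing experiment-wide threshold: "
          f"{shown['pass_experimentwide'].sum()}/{len(shown)}")
    excl = table.query("p_threshold == 0.1 and sample == 'excl_diagnosed'")
    drift = (shown.set_index('outcome')['beta']
             - excl.set_index('outcome')['beta']).abs().max()
    print(f"  max |beta| change when excluding diagnosed children: "
          f"{drift:.3f} (robustness)")
    print(f"table written to {RESULTS / 'pgs_associations.tsv'}")


if __name__ == "__main__":
    main()
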