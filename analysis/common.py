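"""Shared configuration for the numbered analysis drivers.

All drivers analyse the same seeded synthetic study (consortium-scale
discovery GWAS in asymptotic summary mode, 5,919-child target cohort with
13 correlated outcome measures), so each script can rebuild it
deterministically and work on its own stage.
"""

from pathlib import Path

from polylink.simulate import SimConfig, StudyData, simulate_study

STUDY_SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results"


def study_config(seed: int = STUDY_SEED) -> SimConfig:
    return SimConfig(seed=seed)


def get_study(seed: int = STUDY_SEED) -> StudyData:
    return simulate_study(study_config(seed))
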