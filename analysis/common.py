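"""Shared setup for the numbered analysis drivers: the study-scale default
cohort and the output directory."""

from pathlib import Path

from xenopop.synthetic_colonies import SimScenario, simulate_scenario

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def study_cohort():
    RESULTS.mkdir(exist_ok=True)
    return simulate_scenario(SimScenario(seed=SEED))
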