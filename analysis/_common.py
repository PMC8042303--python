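"""Shared setup for the numbered analysis drivers.

All drivers analyse the same fixed-seed synthetic study so their outputs are
mutually consistent; bulky intermediate inputs go to scratch/, small result
tables to results/.
"""

from pathlib import Path

from crelink.simulate import SimConfig, simulate

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
STUDY_SEED = 1


def get_sim():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    return simulate(SimConfig(seed=STUDY_SEED))
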