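"""Shared study conditions for the analysis scripts.

Every driver regenerates the same synthetic channel deterministically
instead of shipping a trajectory: the generator is seeded and cheap.
The system: default pentameric channel (2.25 Å constriction at the 9'
level), a 12° kink on subunit A, 30 ethanol-like ligands over 3000 bulk
waters (1 mol-%), bound/bulk dwell means 150/750 ns, 150 frames at 1 ns.
"""

from pathlib import Path

SEED = 2024
N_FRAMES = 150
DT_NS = 1.0
KINK_DEG = 12.0

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def study_spec():
    from chancav.synthetic import ChannelSpec

    return ChannelSpec(seed=SEED,
                       kink_angles_deg=(KINK_DEG, 0.0, 0.0, 0.0, 0.0))


def study_trajectory():
    from chancav.synthetic import simulate_trajectory

    return simulate_trajectory(study_spec(), N_FRAMES, DT_NS, seed=SEED)


def ensure_dirs():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
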