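"""Shared configuration for the analysis drivers.

Every driver rebuilds its inputs deterministically from SEED, so the scripts
can be run independently and in any order; results land under results/.
"""

from pathlib import Path

import earmorph as em

SEED = 1
SIZE_SCALE = 0.5  # fraction of the emulated clinical group sizes
RESULTS = Path(__file__).resolve().parent.parent / "results"


def training_config() -> em.SimulationConfig:
    return em.SimulationConfig(size_scale=SIZE_SCALE, seed=SEED)


def validation_config() -> em.SimulationConfig:
    return em.SimulationConfig(
        group_sizes=dict(em.simulate.DEFAULT_VALIDATION_SIZES),
        role="validation",
        seed=SEED + 1_000_003,
    )


def build_state():
    """Simulate and run the morphometric stage (the slow shared step)."""
    training = em.simulate_cohort(training_config())
    validation = em.simulate_cohort(validation_config())
    state = em.process_landmarks(training)
    return training, validation, state
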