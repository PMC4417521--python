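"""Deterministic random-stream management.

One root seed drives a whole study run.  Each stage (household synthesis,
risk-factor allocation, eligibility draws, per-arm uptake draws, household
compliance labels) gets its own child stream, derived from the root seed via
``numpy.random.SeedSequence`` spawn keys.  Because the keys are fixed per
stage, re-running a scenario with a different uptake seed leaves the
synthesized population bit-identical.
"""

from __future__ import annotations

import numpy as np

# Fixed spawn keys, one per simulation stage.
STREAMS = {
    "demographics": 0,
    "risk": 1,
    "eligibility": 2,
    "uptake_control": 3,
    "uptake_intervention": 4,
    "compliance": 5,
}


def stream(seed: int, name: str) -> np.random.Generator:
    """Return the named child generator of the root ``seed``."""
    try:
        key = STREAMS[name]
    except KeyError:
        raise KeyError(f"unknown stream {name!r}; known: {sorted(STREAMS)}") from None
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))
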