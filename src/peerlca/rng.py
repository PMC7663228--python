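"""Deterministic per-component random streams.

One root seed drives the whole pipeline. Each component (cohort draw,
missingness, ballots, epoch streams, model starts, bootstraps, ...) gets its
own child stream derived from the root via a fixed spawn key, so adding or
re-running one component never perturbs the draws of another.
"""

from __future__ import annotations

import numpy as np

# Fixed registry: component name -> spawn key. Never reorder; append only.
_COMPONENTS = {
    "cohort": 0,
    "missingness": 1,
    "ballots": 2,
    "epochs": 3,
    "fit": 4,
    "blrt": 5,
    "bootstrap": 6,
    "selection": 7,
    "validation": 8,
    "supporters": 9,
}


def child_rng(seed: int, component: str, index: int = 0) -> np.random.Generator:
    """Return the deterministic child generator for one pipeline component.

    ``index`` separates repeated uses within a component (e.g. bootstrap
    replicate b, participant i) without consuming each other's streams.
    """
    try:
        key = _COMPONENTS[component]
    except KeyError:
        raise KeyError(
            f"unknown component {component!r}; known: {sorted(_COMPONENTS)}"
        ) from None
    ss = np.random.SeedSequence(int(seed), spawn_key=(key, int(index)))
    return np.random.default_rng(ss)


def as_rng(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed or Generator into a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
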