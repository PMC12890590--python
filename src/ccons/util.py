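"""Small shared helpers: randomness plumbing and environment labels."""

from __future__ import annotations

import numpy as np

#: Canonical environments in fixed tie-break order.
ENV_ORDER: tuple[str, ...] = ("animal", "marine", "freshwater", "plant", "soil")

#: Label used for samples/OTUs without an environment assignment.
UNASSIGNED = "unassigned"


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Return a numpy Generator from a seed, an existing Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def combo_key(env_a: str | None, env_b: str | None) -> str:
    """Canonical unordered environment-combination label, e.g. ``animal-soil``.

    ``None`` maps to :data:`UNASSIGNED`.  The two labels are sorted so that
    the key does not depend on pair orientation.
    """
    a = env_a if env_a is not None else UNASSIGNED
    b = env_b if env_b is not None else UNASSIGNED
    lo, hi = sorted((a, b))
    return f"{lo}-{hi}"
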