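"""Shared helpers: seeding, validation, small numerics."""

from __future__ import annotations

import numpy as np

MAX_SEED = 2**31 - 1


def rng_from(seed) -> np.random.Generator:
    """Return a Generator from a seed, Generator, or SeedSequence."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def child_seeds(seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent child seeds (< 2**31) from one parent seed."""
    ss = np.random.SeedSequence(int(seed))
    return np.asarray([int(s) % MAX_SEED for s in ss.generate_state(n)])


def check_positive(name: str, value: float) -> None:
    if not np.all(np.asarray(value) > 0):
        raise ValueError(f"{name} must be positive, got {value!r}")


def db_to_power(level_db: float) -> float:
    """Sound level in dB -> linear power (re the 0 dB reference)."""
    return 10.0 ** (np.asarray(level_db, dtype=float) / 10.0)
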