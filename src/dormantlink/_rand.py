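"""Seed management.

A run is driven by one integer seed. Each stage derives an independent
child generator via :func:`child_rng`, keyed by a stage label, so that
adding or reordering stages never perturbs the randomness of the others.
The splitting rule is ``SeedSequence([seed, crc32(label)])``.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_seed(seed: int, label: str) -> np.random.SeedSequence:
    """Derive a stage-specific seed sequence from the run seed and a label."""
    return np.random.SeedSequence([int(seed), zlib.crc32(label.encode("utf-8"))])


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for one named stage of a run."""
    return np.random.default_rng(child_seed(seed, label))
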