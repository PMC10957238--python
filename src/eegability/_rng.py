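"""Seed-derivation helpers.

Every stochastic entry point takes an integer ``seed``. Internally a stage
derives independent child streams with :class:`numpy.random.SeedSequence`
keyed on a stable stage label, so stages can be re-run in isolation without
stream reuse.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["rng_for", "child_seed"]


def _label_key(label: str) -> int:
    return zlib.crc32(label.encode("utf-8"))


def rng_for(seed: int, label: str = "") -> np.random.Generator:
    """Return a Generator for ``seed``, optionally namespaced by ``label``."""
    if label:
        ss = np.random.SeedSequence([int(seed), _label_key(label)])
    else:
        ss = np.random.SeedSequence(int(seed))
    return np.random.default_rng(ss)


def child_seed(seed: int, label: str) -> int:
    """Derive a deterministic child seed (< 2**31) for a named stage."""
    ss = np.random.SeedSequence([int(seed), _label_key(label)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
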