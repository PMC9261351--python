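"""Shared helpers: seeded substreams, percentile cuts, TSV float formatting."""

from __future__ import annotations

import math

import numpy as np

from .errors import InputError

# Named substreams spawned from one master seed, so re-running a single
# generator component reproduces its output without replaying the others.
_COMPONENT_KEYS = {
    "compendium": 1,
    "ko": 2,
    "hct_library": 3,
    "annotations": 4,
    "peaks": 5,
}


def component_rng(master_seed: int, component: str) -> np.random.Generator:
    """Return a Generator for a named simulation component.

    Substreams are derived from ``SeedSequence(master_seed, spawn_key=(k,))``
    with a fixed per-component key, so each component's stream depends only on
    the master seed and its own name.
    """
    try:
        key = _COMPONENT_KEYS[component]
    except KeyError:
        raise ValueError(f"unknown simulation component {component!r}") from None
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(key,)))


def top_count(n_total: int, pct: float) -> int:
    """Number of top-ranked items in the ``pct``-th percentile band.

    Uses the ceiling rule: the top ``ceil((100 - pct)/100 * n)`` items, which
    guarantees a non-empty cut for pct < 100 (e.g. 627 of 12525 at pct=95).
    """
    if not 0 <= pct < 100:
        raise InputError(f"percentile cut must be in [0, 100), got {pct}")
    if n_total < 1:
        raise InputError("empty ranking")
    return math.ceil((100.0 - pct) / 100.0 * n_total)


def fmt_float(x: float) -> str:
    """Render a float with 6 significant digits for stable TSV output."""
    return f"{x:.6g}"
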