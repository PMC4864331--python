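"""Shared helpers: named random substreams and integer apportionment."""
from __future__ import annotations

import zlib

import numpy as np


def substream(seed, *tags) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a tuple of string tags.

    Streams for different tags are statistically independent, and a stream's
    output does not depend on which other tags exist.  This is what lets the
    null model add or drop a city without perturbing the draws of the others.
    A ``None`` seed gives a fresh nondeterministic stream.
    """
    if seed is None:
        return np.random.default_rng()
    keys = [zlib.crc32(str(t).encode("utf8")) for t in tags]
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + keys))


def largest_remainder(weights, n: int) -> np.ndarray:
    """Apportion ``n`` items to classes proportionally to ``weights``.

    Floor + largest-remainder rule; ties broken by class order (stable sort).
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with a positive sum")
    raw = w / w.sum() * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base
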