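"""Shared helpers: seeded RNG fan-out and transparent gzip IO."""

from __future__ import annotations

import gzip
import io
from pathlib import Path

import numpy as np

MAX_SEED = 2**31 - 1


def spawn_rngs(seed: int | None, n: int) -> list[np.random.Generator]:
    """Expand one run-level seed into ``n`` independent generators.

    Every stochastic stage of the pipeline receives its own stream so that
    adding reads to one stage never perturbs another.
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def child_seed(seed: int | None, index: int) -> int:
    """A derived integer seed (< 2**31) for APIs that want a plain int."""
    ss = np.random.SeedSequence(seed)
    return int(ss.spawn(index + 1)[index].generate_state(1)[0] % MAX_SEED)


def open_text(path: str | Path, mode: str = "rt"):
    """Open a possibly-gzipped text file by extension."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def is_handle(obj) -> bool:
    return isinstance(obj, io.IOBase) or hasattr(obj, "read")
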