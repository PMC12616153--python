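"""Deterministic random-stream management.

A single master seed feeds every generator through an explicit
stream-splitting scheme: each named stream gets its own
``numpy.random.Generator`` spawned from a :class:`numpy.random.SeedSequence`
with a fixed spawn key, so regenerating one synthetic component never
perturbs the draws of another.  Per-ROI bootstrap seeds are derived from
(master seed, ROI name) so adding or removing ROIs leaves the resamples of
the remaining ROIs untouched.
"""

from __future__ import annotations

import hashlib

import numpy as np

# Fixed spawn keys, one per synthetic-data generator.
STREAMS = {
    "cohort": 0,
    "trials": 1,
    "roi_features": 2,
    "phantom": 3,
}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Return the dedicated Generator for a named stream under a master seed."""
    if stream not in STREAMS:
        raise KeyError(f"unknown random stream {stream!r}; known: {sorted(STREAMS)}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(STREAMS[stream],))
    return np.random.default_rng(ss)


def child_seed(master_seed: int, name: str) -> int:
    """Derive a stable 31-bit child seed from a master seed and a label.

    Used for per-ROI bootstrap streams; stable across platforms and runs.
    """
    digest = hashlib.sha256(f"{int(master_seed)}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
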