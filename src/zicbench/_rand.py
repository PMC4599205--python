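"""Deterministic per-stage random substreams.

One global integer seed drives the whole pipeline; each stage derives its
own independent generator from (seed, stage-name) so stages can be re-run
in isolation with stable randomness.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Generator for ``stage`` derived from the global ``seed``.

    ``index`` distinguishes repeated invocations of the same stage
    (e.g. simulation replicates).
    """
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key, int(index)]))
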