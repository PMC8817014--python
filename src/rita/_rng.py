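"""Named, order-independent random substreams derived from one master seed."""

from __future__ import annotations

import zlib

import numpy as np


def _key_ints(key: tuple) -> tuple[int, ...]:
    out = []
    for k in key:
        if isinstance(k, str):
            out.append(zlib.crc32(k.encode("utf-8")))
        else:
            out.append(int(k))
    return tuple(out)


def substream(seed: int, *key) -> np.random.Generator:
    """A Generator keyed by (seed, *key).

    Keys may mix strings (hashed stably) and integers, so e.g. the stream for
    policy "rita" does not depend on the order policies are listed in.
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=_key_ints(key))
    return np.random.default_rng(ss)
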