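"""Shared helpers: seeded RNG substreams and TSV I/O conventions."""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd


def rng_for(seed: int, *tags) -> np.random.Generator:
    """Deterministic substream keyed by ``seed`` and a tuple of tags.

    Strings are hashed with crc32 so the same tag always selects the same
    stream; integers are used as-is.  All randomness in the package flows
    through this helper so a single pipeline seed reproduces every stage.
    """
    keys = [int(seed) & 0x7FFFFFFF]
    for t in tags:
        if isinstance(t, str):
            keys.append(zlib.crc32(t.encode()) & 0x7FFFFFFF)
        else:
            keys.append(int(t) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(keys))


def write_tsv(df: pd.DataFrame, path, float_format: str = "%.9f") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
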