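"""Reference 96-channel substitution signature matrices.

A signature matrix is a DataFrame indexed by the 96 canonical channels
(:data:`formhaem.contexts.CHANNELS_96`) with one unit-sum probability
column per signature. Real COSMIC-format tables can be loaded with
:func:`load_signatures`; because those tables are not redistributed here,
:func:`synthetic_signatures` builds a deterministic synthetic stand-in set
with qualitatively distinct shapes for simulation and recovery testing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from formhaem.contexts import CHANNELS_96, split_channel
from formhaem.errors import InputError


def validate_signatures(sig: pd.DataFrame, atol: float = 1e-6) -> pd.DataFrame:
    """Check channel order, non-negativity and unit column sums."""
    if list(sig.index) != list(CHANNELS_96):
        raise InputError("signature matrix must be indexed by the 96 canonical channels in order")
    if (sig.values < 0).any():
        raise InputError("signature probabilities must be non-negative")
    sums = sig.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=atol):
        bad = sums[~np.isclose(sums, 1.0, atol=atol)].index.tolist()
        raise InputError(f"signature columns must sum to 1: {bad}")
    return sig


def load_signatures(path: str) -> pd.DataFrame:
    """Load a signature CSV with a channel column ('Type' or first column)."""
    table = pd.read_csv(path)
    channel_col = "Type" if "Type" in table.columns else table.columns[0]
    table = table.set_index(channel_col)
    table = table.reindex(CHANNELS_96)
    if table.isna().any().any():
        raise InputError(f"signature table at {path} is missing channels")
    return validate_signatures(table)


def synthetic_signatures(seed: int = 20201) -> pd.DataFrame:
    """Deterministic synthetic signature set (five distinct shapes).

    This is a synthetic stand-in for a reference catalog, not a copy of any
    published signature. The shapes are chosen to be mutually well
    separated and biologically plausible:

    * ``clocklike-cpg``: C>T dominated, strongest at NpCpG contexts.
    * ``ta-heavy``: T>A transversions with a side of T>C — the shape of an
      adenine-adducting mutagen.
    * ``flat``: near-uniform background across all 96 channels.
    * ``ca-oxidative``: C>A dominated (oxidative-damage-like).
    * ``tc-transition``: T>C dominated.
    """
    rng = np.random.default_rng(seed)
    n = len(CHANNELS_96)

    def jitter(weights: np.ndarray) -> np.ndarray:
        w = weights * rng.lognormal(0.0, 0.25, size=n)
        return w / w.sum()

    def type_profile(type_weights: dict[str, float], cpg_boost: float = 1.0) -> np.ndarray:
        w = np.empty(n)
        for i, channel in enumerate(CHANNELS_96):
            five, ref, alt, three = split_channel(channel)
            base = type_weights.get(f"{ref}>{alt}", 0.02)
            if cpg_boost != 1.0 and ref == "C" and three == "G":
                base *= cpg_boost
            w[i] = base
        return jitter(w)

    columns = {
        "clocklike-cpg": type_profile({"C>T": 1.0}, cpg_boost=6.0),
        "ta-heavy": type_profile({"T>A": 1.0, "T>C": 0.35}),
        "flat": jitter(np.ones(n)),
        "ca-oxidative": type_profile({"C>A": 1.0}),
        "tc-transition": type_profile({"T>C": 1.0}),
    }
    sig = pd.DataFrame(columns, index=list(CHANNELS_96))
    return validate_signatures(sig)
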