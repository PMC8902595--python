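"""Small shared helpers (seed derivation, connectivity structures)."""

from __future__ import annotations

import hashlib

import numpy as np
from scipy import ndimage

#: Allowed connected-component neighbourhood tags (faces / faces+edges /
#: faces+edges+corners).
CONNECTIVITIES = (6, 18, 26)


def derive_seed(base_seed: int, *parts: object) -> int:
    """Derive a reproducible sub-seed from a base seed and a label path.

    Hash-based so that distinct stage/repeat labels never collide by
    arithmetic accident; always < 2**31 so it is a valid seed everywhere.
    """
    key = "|".join([str(int(base_seed))] + [str(p) for p in parts])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3x3x3 boolean structuring element for 6/18/26 connectivity."""
    if connectivity not in CONNECTIVITIES:
        raise ValueError(f"connectivity must be one of {CONNECTIVITIES}, got {connectivity}")
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, rank)


def as_int_tuple3(value, name: str) -> tuple[int, int, int]:
    t = tuple(int(v) for v in value)
    if len(t) != 3:
        raise ValueError(f"{name} must have 3 entries, got {len(t)}")
    return t  # type: ignore[return-value]


def as_float_tuple3(value, name: str) -> tuple[float, float, float]:
    t = tuple(float(v) for v in value)
    if len(t) != 3:
        raise ValueError(f"{name} must have 3 entries, got {len(t)}")
    return t  # type: ignore[return-value]
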