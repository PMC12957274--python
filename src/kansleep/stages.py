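"""Sleep-stage label coding.

The five AASM stages are integer-coded in a fixed order used everywhere in
the package (confusion matrices, transition matrices, class counts):

    0 = W (wake), 1 = N1, 2 = N2, 3 = N3, 4 = REM
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np


class Stage(IntEnum):
    """AASM sleep stage, integer-coded 0-4 in the order W, N1, N2, N3, REM."""

    W = 0
    N1 = 1
    N2 = 2
    N3 = 3
    REM = 4


STAGE_NAMES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")
N_STAGES: int = 5

_NAME_TO_CODE = {name: i for i, name in enumerate(STAGE_NAMES)}


def stages_from_tokens(tokens) -> np.ndarray:
    """Map stage name tokens (``W``/``N1``/.../``REM``) to integer codes.

    Raises ``ValueError`` naming the first unrecognized token.
    """
    out = np.empty(len(tokens), dtype=np.int64)
    for i, tok in enumerate(tokens):
        t = str(tok).strip()
        if t not in _NAME_TO_CODE:
            raise ValueError(f"unknown sleep stage token {t!r}")
        out[i] = _NAME_TO_CODE[t]
    return out


def tokens_from_stages(stages) -> list[str]:
    """Inverse of :func:`stages_from_tokens`."""
    arr = np.asarray(stages, dtype=np.int64)
    if arr.size and (arr.min() < 0 or arr.max() >= N_STAGES):
        raise ValueError("stage code outside 0..4")
    return [STAGE_NAMES[int(s)] for s in arr]
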