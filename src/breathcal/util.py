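"""Small shared helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["round_half_up"]


def round_half_up(x, decimals: int = 0):
    """Round with ties going away from zero at the last kept decimal.

    Used wherever a reading or a reported figure is rounded, so that the
    convention is fixed rather than platform banker's rounding.  Works on
    scalars and arrays.
    """
    factor = 10.0 ** decimals
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    if out.ndim == 0:
        return float(out)
    return out
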