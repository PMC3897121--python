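"""Small shared numeric helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["round_half_away", "pct"]


def round_half_away(x, decimals: int = 0):
    """Round with halves going away from zero (printed-table convention).

    ``numpy.round`` / builtin ``round`` use banker's rounding; published
    summary tables round 0.5 up in magnitude instead.
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    if out.ndim == 0:
        val = float(out)
        return int(val) if decimals == 0 else val
    return out


def pct(count, total, decimals: int = 1):
    """Percentage of ``count`` in ``total`` rounded half-away-from-zero."""
    if total == 0:
        return 0.0
    return float(round_half_away(100.0 * count / total, decimals))
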