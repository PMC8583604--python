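"""Benjamini–Hochberg step-up false-discovery-rate adjustment.

The study tests 17 outcomes per effect column; each column is treated
as its own family of m = 17 p-values.  The adjusted value for the i-th
smallest raw p is

    p_adj_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1,

mapped back to the original order.  The adjustment is monotone (ties
and order are preserved) and never smaller than the raw p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["PValueFamily", "bh_adjust"]


@dataclass(frozen=True)
class PValueFamily:
    """A named family of raw p-values sharing one FDR adjustment."""

    raw_p: Sequence[float]
    labels: Optional[Sequence[str]] = None
    family_label: str = ""

    def __post_init__(self):
        if self.labels is not None and len(self.labels) != len(self.raw_p):
            raise ValueError("labels and raw_p lengths differ")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values, in the input order.

    NaNs (untestable outcomes) are passed through and do not count
    toward the family size.
    """
    if isinstance(p_values, PValueFamily):
        p_values = p_values.raw_p
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    q = p[ok]
    if ((q < 0) | (q > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = q.size
    if m == 0:
        return out
    order = np.argsort(q, kind="stable")
    scaled = q[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    restored = np.empty(m)
    restored[order] = adjusted
    out[ok] = restored
    return out
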