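"""Seizure-onset-zone estimation from a fragility matrix.

Each electrode's fragility values are aggregated across time windows (mean,
median, max, or min), the electrodes are ranked by the aggregate, and the
top N are proposed as the SOZ, with N a proportion (default 10%) of the
electrode count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["SozEstimate", "estimate_soz"]

_METHODS = {
    "mean": np.mean,
    "median": np.median,
    "max": np.max,
    "min": np.min,
}


@dataclass(frozen=True)
class SozEstimate:
    """Ranked electrodes with aggregated fragility scores and the top-N set."""

    ranked_electrodes: list[str]
    scores: np.ndarray  # aligned with ranked_electrodes, descending
    selected: list[str]
    method: str
    proportion: float

    def to_frame(self) -> pd.DataFrame:
        sel = set(self.selected)
        return pd.DataFrame({
            "electrode": self.ranked_electrodes,
            "score": self.scores,
            "selected": [e in sel for e in self.ranked_electrodes],
        })

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"SozEstimate(method={self.method!r}, proportion={self.proportion}, "
                f"selected={self.selected})")


def estimate_soz(frag, method: str = "mean", proportion: float = 0.1,
                 time_range: tuple[int, int] | None = None) -> SozEstimate:
    """Aggregate fragility over time and rank electrodes for SOZ candidacy.

    Parameters
    ----------
    frag : FragilityResults
        Output of the fragility computation.
    method : {'mean', 'median', 'max', 'min'}
        Aggregation across time windows.
    proportion : float in (0, 1]
        Fraction of electrodes to select; ``N = max(1, round(proportion*M))``
        with half-away-from-zero rounding.
    time_range : (start, stop) window indices, optional
        Half-open window-index range to aggregate over (e.g. post-onset
        windows only); default uses every window.
    """
    if method not in _METHODS:
        raise ValueError(
            f"invalid method {method!r}; valid options are {sorted(_METHODS)}"
        )
    if not (0 < proportion <= 1):
        raise ValueError(f"proportion must be in (0, 1], got {proportion}")
    mat = np.asarray(frag.fragility, dtype=np.float64)
    m, w = mat.shape
    if time_range is not None:
        a, b = time_range
        if not (0 <= a < b <= w):
            raise ValueError(f"time_range {time_range} outside [0, {w})")
        mat = mat[:, a:b]
    scores = _METHODS[method](mat, axis=1)
    # Stable sort keeps input electrode order on ties.
    order = np.argsort(-scores, kind="stable")
    if np.unique(scores).size < m:
        logger.info("tied aggregated scores broken by input electrode order")
    n_sel = max(1, int(math.floor(proportion * m + 0.5)))
    ranked = [frag.electrodes[i] for i in order]
    return SozEstimate(
        ranked_electrodes=ranked,
        scores=scores[order],
        selected=ranked[:n_sel],
        method=method,
        proportion=float(proportion),
    )
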