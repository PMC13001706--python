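"""Annotated multichannel iEEG container.

An :class:`Epoch` holds an M-electrode-by-N-timepoint voltage matrix
(microvolts) together with the metadata needed for seizure analysis:
electrode names, per-electrode annotations (``soz``, ``resected``), the
sampling rate, the time of the first sample relative to seizure onset
(onset = 0 s), and free-form patient metadata.  All subsetting operations
keep the per-electrode metadata aligned with the data rows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = ["Epoch", "make_epoch"]


@dataclass
class Epoch:
    """An iEEG voltage matrix with aligned electrode and patient metadata.

    Parameters
    ----------
    data : ndarray, shape (M, N)
        Voltage in microvolts; one row per electrode.
    electrodes : list of str
        M unique, non-empty electrode names.
    start_time : float
        Time of the first sample in seconds relative to seizure onset
        (onset = 0); sample ``j`` occurs at ``start_time + j / sampling_rate``.
    sampling_rate : float
        Sampling frequency in Hz, strictly positive.
    row_data : DataFrame, optional
        M rows of per-electrode attributes (e.g. boolean columns ``soz``,
        ``resected``).  Defaults to an empty table with M rows.
    meta_data : dict, optional
        Open key/value patient or recording attributes.
    """

    data: np.ndarray
    electrodes: list[str]
    start_time: float
    sampling_rate: float
    row_data: pd.DataFrame | None = None
    meta_data: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (electrodes x time), got ndim={self.data.ndim}")
        self.electrodes = [str(e) for e in self.electrodes]
        m, n = self.data.shape
        if n < 1:
            raise ValueError("data must contain at least one timepoint")
        if len(self.electrodes) != m:
            raise ValueError(
                f"electrodes: expected {m} names to match data rows, got {len(self.electrodes)}"
            )
        if any(e == "" for e in self.electrodes):
            raise ValueError("electrodes: names must be non-empty")
        if len(set(self.electrodes)) != m:
            dups = sorted({e for e in self.electrodes if self.electrodes.count(e) > 1})
            raise ValueError(f"electrodes: duplicate names {dups}")
        if not (self.sampling_rate > 0):
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        self.start_time = float(self.start_time)
        self.sampling_rate = float(self.sampling_rate)
        if self.row_data is None:
            self.row_data = pd.DataFrame(index=range(m))
        else:
            self.row_data = pd.DataFrame(self.row_data).reset_index(drop=True)
            if len(self.row_data) != m:
                raise ValueError(
                    f"row_data: expected {m} rows to match data rows, got {len(self.row_data)}"
                )
        self.meta_data = dict(self.meta_data)

    # -- basic geometry ----------------------------------------------------

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Timestamps of every sample, in seconds relative to onset."""
        return self.start_time + np.arange(self.n_times) / self.sampling_rate

    @property
    def end_time(self) -> float:
        """Timestamp of the last sample."""
        return self.start_time + (self.n_times - 1) / self.sampling_rate

    def electrode_indices(self, names: Sequence[str]) -> list[int]:
        """Map electrode names to row indices, erroring on unknown names."""
        lookup = {e: i for i, e in enumerate(self.electrodes)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"unknown electrode name(s): {missing}")
        return [lookup[n] for n in names]

    def soz_mask(self) -> np.ndarray:
        """Boolean SOZ flags from ``row_data['soz']`` (all-false if absent)."""
        return self._bool_column("soz")

    def resected_mask(self) -> np.ndarray:
        return self._bool_column("resected")

    def _bool_column(self, name: str) -> np.ndarray:
        if name in self.row_data.columns:
            return self.row_data[name].to_numpy(dtype=bool)
        logger.warning("row_data has no %r column; treating all electrodes as False", name)
        return np.zeros(self.n_electrodes, dtype=bool)

    # -- subsetting --------------------------------------------------------

    def subset(
        self,
        electrode_index: Sequence[int | str] | None = None,
        time_index: Sequence[int] | None = None,
    ) -> "Epoch":
        """Select electrodes and/or a contiguous run of timepoints.

        Electrode selection may mix 0-based row indices and electrode names;
        the per-electrode table is subset row-for-row with the data.  The time
        selection must be a contiguous, increasing run of sample indices so
        that the result still has a well-defined ``start_time`` and
        ``sampling_rate``.
        """
        m, n = self.data.shape
        if electrode_index is None:
            rows = list(range(m))
        else:
            rows = []
            for ix in electrode_index:
                if isinstance(ix, str):
                    rows.append(self.electrode_indices([ix])[0])
                else:
                    ix = int(ix)
                    if not (0 <= ix < m):
                        raise IndexError(f"electrode index {ix} out of range for M={m}")
                    rows.append(ix)
        if time_index is None:
            cols = np.arange(n)
        else:
            cols = np.asarray(time_index, dtype=np.intp)
            if cols.size == 0:
                raise IndexError("time_index must be non-empty")
            if cols.min() < 0 or cols.max() >= n:
                raise IndexError(
                    f"time index out of range: [{cols.min()}, {cols.max()}] for N={n}"
                )
            if cols.size > 1 and not np.array_equal(cols, np.arange(cols[0], cols[-1] + 1)):
                raise ValueError(
                    "time_index must be a contiguous increasing run of samples "
                    "(arbitrary scatters would leave start_time/sampling_rate undefined)"
                )
        new_start = self.start_time + int(cols[0]) / self.sampling_rate
        return Epoch(
            data=self.data[np.ix_(rows, cols)].copy(),
            electrodes=[self.electrodes[i] for i in rows],
            start_time=new_start,
            sampling_rate=self.sampling_rate,
            row_data=self.row_data.iloc[rows],
            meta_data=self.meta_data,
        )

    def __getitem__(self, key) -> "Epoch":
        """``epoch[elec_idx, time_idx]`` shorthand for :meth:`subset`.

        Slices are accepted for either axis; ``time_idx`` slices must have
        step 1.
        """
        if not isinstance(key, tuple) or len(key) != 2:
            raise TypeError("expected epoch[electrode_index, time_index]")
        eix, tix = key
        eix = self._expand_key(eix, self.n_electrodes)
        tix = self._expand_key(tix, self.n_times)
        return self.subset(eix, tix)

    @staticmethod
    def _expand_key(key, size: int):
        if key is None or (isinstance(key, slice) and key == slice(None)):
            return None
        if isinstance(key, slice):
            if key.step not in (None, 1):
                raise ValueError("slice step must be 1")
            return list(range(*key.indices(size)))
        if isinstance(key, (int, np.integer, str)):
            return [key]
        return list(key)

    # -- time operations ---------------------------------------------------

    def crop(self, start: float, end: float) -> "Epoch":
        """Keep samples whose timestamp ``t`` satisfies ``start <= t < end``.

        The interval is half-open so that adjacent crops tile the epoch
        without duplicating boundary samples.
        """
        if not (start < end):
            raise ValueError(f"crop requires start < end, got [{start}, {end})")
        rate = self.sampling_rate
        # Round to the sample grid with a small guard against float jitter.
        eps = 1e-9
        j0 = math.ceil((start - self.start_time) * rate - eps)
        j1 = math.ceil((end - self.start_time) * rate - eps)  # exclusive
        j0 = max(j0, 0)
        j1 = min(j1, self.n_times)
        if j0 >= j1:
            raise ValueError(
                f"crop [{start}, {end}) does not intersect the epoch, which spans "
                f"[{self.start_time}, {self.end_time + 1 / rate}) s"
            )
        return self.subset(None, list(range(j0, j1)))

    def resample(self, new_rate: float) -> "Epoch":
        """Resample every channel to ``new_rate`` Hz.

        Polyphase filtering (:func:`scipy.signal.resample_poly`) with an
        anti-aliasing low-pass at the new Nyquist; resampling to the current
        rate is a bit-exact passthrough.  The output has
        ``round(N * new_rate / old_rate)`` samples.
        """
        if not (new_rate > 0):
            raise ValueError(f"new_rate must be > 0, got {new_rate}")
        new_rate = float(new_rate)
        if new_rate == self.sampling_rate:
            return Epoch(
                self.data.copy(), list(self.electrodes), self.start_time,
                self.sampling_rate, self.row_data, self.meta_data,
            )
        ratio = Fraction(new_rate / self.sampling_rate).limit_denominator(10000)
        up, down = ratio.numerator, ratio.denominator
        out = signal.resample_poly(self.data, up, down, axis=1)
        target = int(round(self.n_times * new_rate / self.sampling_rate))
        target = max(target, 1)
        out = out[:, :target]
        return Epoch(
            out, list(self.electrodes), self.start_time, new_rate,
            self.row_data, self.meta_data,
        )

    # -- plotting ----------------------------------------------------------

    def plot_raw(self, highlight: Sequence[str] = (), scale: float | None = None, ax=None):
        """Stacked-offset voltage traces, one per electrode.

        Highlighted electrodes (typically clinical SOZ / resected channels)
        are drawn in red; a vertical line marks seizure onset at t = 0.
        Returns the matplotlib figure.
        """
        import matplotlib.pyplot as plt

        hl = set(highlight)
        self.electrode_indices(list(hl))  # validates names
        if ax is None:
            fig, ax = plt.subplots(figsize=(10, max(3, 0.4 * self.n_electrodes)))
        else:
            fig = ax.figure
        if scale is None:
            spread = np.percentile(np.abs(self.data), 98) if self.data.size else 1.0
            scale = max(float(spread) * 2.0, 1e-12)
        t = self.times
        for i, name in enumerate(self.electrodes):
            offset = (self.n_electrodes - 1 - i) * scale
            color = "red" if name in hl else "black"
            ax.plot(t, self.data[i] + offset, color=color, linewidth=0.6)
        ax.axvline(0.0, color="tab:blue", linestyle="--", linewidth=1.0)
        ax.set_yticks([(self.n_electrodes - 1 - i) * scale for i in range(self.n_electrodes)])
        ax.set_yticklabels(self.electrodes)
        for label, name in zip(ax.get_yticklabels(), self.electrodes):
            if name in hl:
                label.set_color("red")
        ax.set_xlabel("time relative to onset (s)")
        ax.set_ylabel("electrode")
        return fig


def make_epoch(
    data: np.ndarray,
    electrodes: Sequence[str],
    start_time: float,
    sampling_rate: float,
    row_data: pd.DataFrame | None = None,
    meta_data: Mapping[str, Any] | None = None,
) -> Epoch:
    """Construct a validated :class:`Epoch` from an iEEG matrix and metadata."""
    return Epoch(
        data=np.asarray(data, dtype=np.float64),
        electrodes=list(electrodes),
        start_time=start_time,
        sampling_rate=sampling_rate,
        row_data=row_data,
        meta_data=dict(meta_data or {}),
    )
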