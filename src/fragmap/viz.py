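"""Visualization of fragility results.

Three views mirror standard fragility reporting: a spatiotemporal heatmap of
the full M x W matrix, per-group mean traces over time with a dispersion
band, and per-group quantile bands.  Every plot's underlying numbers are
available as a DataFrame (``group_stats`` / ``group_quantiles``), so tests
assert numerical summaries rather than pixels; each figure also carries its
table as ``fig.frag_table``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fragility import FragilityResults

__all__ = [
    "GroupSpec",
    "group_stats",
    "group_quantiles",
    "plot_heatmap",
    "plot_frag_distribution",
    "plot_frag_quantile",
]


@dataclass(frozen=True)
class GroupSpec:
    """A highlighted electrode group (e.g. clinical SOZ) and its complement."""

    group_index: tuple = ()
    labels: tuple[str, str] = ("SOZ", "REF")

    @classmethod
    def from_soz(cls, frag: FragilityResults) -> "GroupSpec":
        if frag.soz_mask is None:
            raise ValueError("fragility result carries no SOZ mask")
        return cls(tuple(np.nonzero(frag.soz_mask)[0]))


def _resolve_group(frag: FragilityResults, group: GroupSpec) -> np.ndarray:
    """Indices of the group's electrodes, validating names/bounds."""
    idx = []
    for g in group.group_index:
        if isinstance(g, str):
            if g not in frag.electrodes:
                raise KeyError(f"unknown electrode name in group: {g!r}")
            idx.append(frag.electrodes.index(g))
        else:
            g = int(g)
            if not (0 <= g < frag.n_electrodes):
                raise IndexError(f"group electrode index {g} out of range")
            idx.append(g)
    return np.asarray(sorted(set(idx)), dtype=int)


def group_stats(frag: FragilityResults, group: GroupSpec,
                band: str = "sd") -> pd.DataFrame:
    """Per-window mean and dispersion for the group and its complement."""
    if band not in ("sd", "se"):
        raise ValueError(f"band must be 'sd' or 'se', got {band!r}")
    gidx = _resolve_group(frag, group)
    cidx = np.setdiff1d(np.arange(frag.n_electrodes), gidx)
    if gidx.size == 0:
        raise ValueError("group is empty")
    if cidx.size == 0:
        raise ValueError("group covers every electrode; the complement is empty")
    rows = []
    for label, idx in ((group.labels[0], gidx), (group.labels[1], cidx)):
        sub = frag.fragility[idx]
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1) if idx.size > 1 else np.zeros(frag.n_windows)
        disp = sd if band == "sd" else sd / np.sqrt(idx.size)
        rows.append(pd.DataFrame({
            "time": frag.window_centers, "group": label,
            "mean": mean, "band": disp,
        }))
    return pd.concat(rows, ignore_index=True)


def group_quantiles(frag: FragilityResults, group: GroupSpec,
                    quantiles: Sequence[float] | None = None) -> pd.DataFrame:
    """Per-window fragility quantiles for the group and its complement."""
    if quantiles is None:
        quantiles = np.arange(0.1, 0.91, 0.1)
    q = np.asarray(sorted(quantiles), dtype=float)
    if q.size == 0 or q.min() <= 0 or q.max() >= 1:
        raise ValueError("quantiles must lie strictly inside (0, 1)")
    gidx = _resolve_group(frag, group)
    cidx = np.setdiff1d(np.arange(frag.n_electrodes), gidx)
    if gidx.size == 0 or cidx.size == 0:
        raise ValueError("both the group and its complement must be non-empty")
    rows = []
    for label, idx in ((group.labels[0], gidx), (group.labels[1], cidx)):
        quants = np.quantile(frag.fragility[idx], q, axis=0)  # (Q, W)
        for qi, qv in enumerate(q):
            rows.append(pd.DataFrame({
                "time": frag.window_centers, "group": label,
                "quantile": qv, "value": quants[qi],
            }))
    return pd.concat(rows, ignore_index=True)


def plot_heatmap(frag: FragilityResults, group: GroupSpec | None = None,
                 sort_by_fragility: bool = False, ax=None):
    """Spatiotemporal heatmap: electrodes on y, time windows on x.

    Warm colors mark high fragility; color limits follow the data range to
    emphasize regional differences.  Group electrodes' y-labels are drawn in
    red, and a dashed line marks seizure onset (t = 0).
    """
    import matplotlib.pyplot as plt

    order = np.arange(frag.n_electrodes)
    if sort_by_fragility:
        order = np.argsort(frag.fragility.mean(axis=1))
    gset = set(_resolve_group(frag, group)) if group is not None else set()
    if ax is None:
        fig, ax = plt.subplots(figsize=(10, max(3, 0.3 * frag.n_electrodes)))
    else:
        fig = ax.figure
    mat = frag.fragility[order]
    dt = frag.step / frag.sampling_rate
    t0 = frag.window_centers[0] - dt / 2
    t1 = frag.window_centers[-1] + dt / 2
    vmin, vmax = float(mat.min()), float(mat.max())
    if vmax == vmin:
        vmax = vmin + 1e-12
    im = ax.imshow(mat, aspect="auto", origin="upper", cmap="turbo",
                   vmin=vmin, vmax=vmax,
                   extent=(t0, t1, frag.n_electrodes - 0.5, -0.5),
                   interpolation="nearest")
    ax.set_yticks(range(frag.n_electrodes))
    ax.set_yticklabels([frag.electrodes[i] for i in order])
    for pos, i in enumerate(order):
        if i in gset:
            ax.get_yticklabels()[pos].set_color("red")
    if t0 < 0 < t1:
        ax.axvline(0.0, color="white", linestyle="--", linewidth=1.0)
    ax.set_xlabel("time relative to onset (s)")
    ax.set_ylabel("electrode")
    fig.colorbar(im, ax=ax, label="fragility")
    fig.frag_table = frag.to_frame()
    return fig


def plot_frag_distribution(frag: FragilityResults, group: GroupSpec,
                           band: str = "sd", ax=None):
    """Group-mean fragility over time with a +/-1 sd (or se) shaded band."""
    import matplotlib.pyplot as plt

    table = group_stats(frag, group, band=band)
    if ax is None:
        fig, ax = plt.subplots(figsize=(8, 4))
    else:
        fig = ax.figure
    colors = {group.labels[0]: "crimson", group.labels[1]: "gray"}
    for label, sub in table.groupby("group", sort=False):
        ax.plot(sub["time"], sub["mean"], label=label, color=colors.get(label))
        ax.fill_between(sub["time"], sub["mean"] - sub["band"],
                        sub["mean"] + sub["band"], alpha=0.25,
                        color=colors.get(label))
    ax.axvline(0.0, color="k", linestyle="--", linewidth=0.8)
    ax.set_xlabel("time relative to onset (s)")
    ax.set_ylabel("mean fragility")
    ax.legend()
    fig.frag_table = table
    return fig


def plot_frag_quantile(frag: FragilityResults, group: GroupSpec,
                       quantiles: Sequence[float] | None = None, ax=None):
    """Per-window quantile bands for the group versus its complement."""
    import matplotlib.pyplot as plt

    table = group_quantiles(frag, group, quantiles)
    if ax is None:
        fig, ax = plt.subplots(figsize=(8, 4))
    else:
        fig = ax.figure
    colors = {group.labels[0]: "crimson", group.labels[1]: "gray"}
    for (label, qv), sub in table.groupby(["group", "quantile"], sort=False):
        ax.plot(sub["time"], sub["value"], color=colors.get(label),
                alpha=0.5, linewidth=0.8)
    for label in colors:
        ax.plot([], [], color=colors[label], label=label)
    ax.axvline(0.0, color="k", linestyle="--", linewidth=0.8)
    ax.set_xlabel("time relative to onset (s)")
    ax.set_ylabel("fragility quantiles")
    ax.legend()
    fig.frag_table = table
    return fig
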