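"""Synthetic iEEG epochs from piecewise-stationary linear network dynamics.

The generator draws a stable random network A_pre (the interictal baseline),
derives an ictal network A_ictal by strengthening the recurrent excitatory
coupling within a small set of planted "fragile" nodes and pushing the
spectral radius close to 1, and simulates

    x(t+1) = A x(t) + eps,   eps ~ N(0, noise_sd^2 I)

with A switching from A_pre to A_ictal at seizure onset (t = 0).  The planted
nodes dominate the near-unstable mode of A_ictal, so small structured
perturbations at those nodes are destabilizing — giving a known ground truth
against which the whole fragility pipeline can be validated without any
clinical data.

The generator deliberately lives inside the model class the fragility method
assumes (piecewise-stationary linear dynamics), so parameter recovery tests
the pipeline, not model mismatch.  An optional tanh saturation provides a
mild model-mismatch variant for robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .epoch import Epoch
from .system_id import spectral_radius

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "random_stable_system",
    "plant_fragile_nodes",
    "generate",
]

#: Hard amplitude clip, microvolts (physically implausible beyond this).
CLIP_UV = 2000.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic seizure generator.

    Defaults describe a small stereo-EEG-like montage: 12 electrodes at
    500 Hz, 2 s of baseline and 2 s of ictal activity, baseline spectral
    radius 0.85 versus near-critical 0.99 after onset, two planted fragile
    nodes whose mutual excitatory coupling grows five-fold at onset (enough
    for the near-unit mode to load on every planted node), and 20 µV
    process noise (giving tens-of-µV baseline amplitudes).
    """

    n_electrodes: int = 12
    sampling_rate: float = 500.0
    pre_onset_s: float = 2.0
    post_onset_s: float = 2.0
    baseline_radius: float = 0.85
    ictal_radius: float = 0.99
    fragile_nodes: tuple[int, ...] = (3, 7)
    coupling_boost: float = 5.0
    noise_sd: float = 20.0
    seed: int = 0
    tanh_saturation: float | None = None  # optional soft clip scale, off by default

    def __post_init__(self) -> None:
        if self.n_electrodes < 2:
            raise ValueError("need at least 2 electrodes")
        if not (0 <= self.baseline_radius < 1) or not (0 < self.ictal_radius < 1):
            raise ValueError("spectral radii must lie in [0, 1)")
        if self.baseline_radius >= self.ictal_radius:
            raise ValueError("baseline_radius must be below ictal_radius")
        bad = [k for k in self.fragile_nodes if not (0 <= k < self.n_electrodes)]
        if bad:
            raise ValueError(f"fragile node index out of range: {bad}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated epoch plus its ground truth."""

    epoch: Epoch
    truth: tuple[int, ...]  # planted fragile node indices
    spec: SyntheticSpec
    A_pre: np.ndarray
    A_ictal: np.ndarray

    @property
    def truth_names(self) -> list[str]:
        return [self.epoch.electrodes[i] for i in self.truth]


def random_stable_system(m: int, target_radius: float, seed: int) -> np.ndarray:
    """Dense random M x M matrix rescaled to an exact spectral radius."""
    if m < 2:
        raise ValueError("need M >= 2")
    if not (0 <= target_radius < 1):
        raise ValueError(f"target_radius must be in [0, 1), got {target_radius}")
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((m, m))
    if target_radius == 0:
        return np.zeros((m, m))
    return A * (target_radius / spectral_radius(A))


def plant_fragile_nodes(A: np.ndarray, nodes: Sequence[int],
                        coupling_boost: float,
                        target_radius: float) -> np.ndarray:
    """Strengthen recurrent excitation within the planted node set, rescale.

    A rank-one excitatory mode ``(coupling_boost - 1) * rho(A) * w w^T`` is
    added, with ``w`` the unit vector spread uniformly over the planted
    nodes (seizure onset as runaway recurrent excitation within the onset
    zone), and the result is rescaled to ``target_radius``.  For
    ``coupling_boost`` well above 1 the dominant, near-unit mode of the
    returned matrix is ``w`` itself, so it loads on *every* planted node and
    small perturbations of their coupling destabilize the network — the
    planted set is the ground-truth fragile set.  ``coupling_boost = 1``
    reduces to a pure rescale of ``A``.
    """
    nodes = list(nodes)
    if not nodes:
        raise ValueError("nodes must be non-empty")
    B = np.array(A, dtype=np.float64, copy=True)
    w = np.zeros(B.shape[0])
    w[nodes] = 1.0 / np.sqrt(len(nodes))
    B += (coupling_boost - 1.0) * spectral_radius(A) * np.outer(w, w)
    rho = spectral_radius(B)
    if rho == 0:
        raise ValueError("cannot rescale a nilpotent/zero matrix to a target radius")
    return B * (target_radius / rho)


def generate(spec: SyntheticSpec | None = None, **overrides) -> SyntheticDataset:
    """Simulate a seizure epoch with planted fragile nodes.

    Fully reproducible from ``spec.seed``; onset is at t = 0 with
    ``round(pre_onset_s * sampling_rate)`` baseline samples before it.
    """
    if spec is None:
        spec = SyntheticSpec()
    if overrides:
        spec = replace(spec, **overrides)
    m = spec.n_electrodes
    rate = spec.sampling_rate
    n_pre = int(round(spec.pre_onset_s * rate))
    n_post = int(round(spec.post_onset_s * rate))
    n = n_pre + n_post
    if n < 2:
        raise ValueError("epoch too short; increase pre/post duration")

    rng = np.random.default_rng(spec.seed)
    A_pre = random_stable_system(m, spec.baseline_radius, seed=rng.integers(2 ** 31))
    A_ictal = plant_fragile_nodes(A_pre, spec.fragile_nodes,
                                  spec.coupling_boost, spec.ictal_radius)

    x = np.zeros(m)
    data = np.empty((m, n))
    for t in range(n):
        A = A_pre if t < n_pre else A_ictal
        eps = rng.normal(0.0, spec.noise_sd, size=m) if spec.noise_sd > 0 else 0.0
        x = A @ x + eps
        if spec.tanh_saturation:
            x = spec.tanh_saturation * np.tanh(x / spec.tanh_saturation)
        data[:, t] = x
    clipped = np.abs(data) >= CLIP_UV
    if clipped.mean() > 0.10:
        raise ValueError(
            "explosive trajectory: >10% of samples at the amplitude clip; "
            "lower ictal_radius or coupling_boost"
        )
    data = np.clip(data, -CLIP_UV, CLIP_UV)

    names = [f"E{i + 1:02d}" for i in range(m)]
    soz = np.zeros(m, dtype=bool)
    soz[list(spec.fragile_nodes)] = True
    epoch = Epoch(
        data=data,
        electrodes=names,
        start_time=-spec.pre_onset_s,
        sampling_rate=rate,
        row_data=pd.DataFrame({"soz": soz, "resected": soz.copy()}),
        meta_data={
            "generator": "fragmap.synthetic",
            "seed": int(spec.seed),
            "baseline_radius": spec.baseline_radius,
            "ictal_radius": spec.ictal_radius,
        },
    )
    return SyntheticDataset(epoch=epoch, truth=tuple(spec.fragile_nodes),
                            spec=spec, A_pre=A_pre, A_ictal=A_ictal)
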