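"""Neural fragility: minimum-norm structured destabilizing perturbations.

Given a window's estimated linear dynamics x(t+1) = A x(t) with A stable
(spectral radius < 1), the fragility of electrode k measures how small a
structured change to A suffices to make the dynamics marginally unstable.
The perturbation is rank one and confined to a single column (or row) of A:

    column structure:  Delta = gamma e_k^T      (electrode k's outgoing weights)
    row structure:     Delta = e_k gamma^T      (electrode k's incoming weights)

For a target eigenvalue lambda* = sigma + i*omega on the unit circle,
lambda* is an eigenvalue of A + gamma e_k^T iff

    1 + e_k^T (A - lambda* I)^{-1} gamma = 0.

Writing r = ((A - lambda* I)^{-1})^T e_k, this is the pair of real linear
constraints Re(r)^T gamma = -1 and Im(r)^T gamma = 0, whose minimum-two-norm
solution is closed-form: gamma = B^T (B B^T)^{-1} [-1, 0]^T with B stacking
Re(r)^T over Im(r)^T.  The spectral norm of the rank-one Delta equals
||gamma||_2.  An electrode's raw fragility is the minimum such norm over a
grid of target eigenvalues on the upper unit semicircle; each window's raw
norms are then reverse-scaled, (max - value) / max, so the hardest-to-
destabilize electrode maps to 0 and easier ones toward 1.

The sliding-window driver is exposed both as the statsmodels-style
:class:`FragilityModel` / :class:`FragilityResults` pair and as the
:func:`calc_adj_frag` convenience function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from joblib import Parallel, delayed

from .epoch import Epoch
from .system_id import LinearModelFit, fit_window_model, select_lambda

logger = logging.getLogger(__name__)

__all__ = [
    "TargetEigenvalue",
    "PerturbationResult",
    "FragilityResults",
    "FragilityModel",
    "omega_grid",
    "min_norm_perturbation",
    "electrode_fragility",
    "normalize_window",
    "calc_adj_frag",
]

#: Tolerance below which lambda* counts as an existing eigenvalue of A.
_EIG_TOL = 1e-10


@dataclass(frozen=True)
class TargetEigenvalue:
    """A unit-modulus eigenvalue target sigma + i*omega."""

    sigma: float
    omega: float

    def __post_init__(self) -> None:
        if abs(self.sigma ** 2 + self.omega ** 2 - 1.0) > 1e-12:
            raise ValueError(
                f"target eigenvalue must have modulus 1, got |{self.sigma}+i{self.omega}| "
                f"= {np.hypot(self.sigma, self.omega)}"
            )

    @property
    def value(self) -> complex:
        return complex(self.sigma, self.omega)

    @classmethod
    def from_angle(cls, theta: float) -> "TargetEigenvalue":
        s, c = float(np.sin(theta)), float(np.cos(theta))
        # Snap to exactly-real targets: the eigenvalue-placement condition
        # for a real target is a single constraint, and its minimum does not
        # coincide with the omega -> 0 limit of the two-constraint problem.
        if abs(s) < 1e-12:
            s, c = 0.0, (1.0 if c > 0 else -1.0)
        return cls(c, s)


@dataclass(frozen=True)
class PerturbationResult:
    """Minimum-norm rank-one perturbation placing ``target`` in the spectrum.

    ``gamma`` is the nonzero row/column of the perturbation matrix; ``norm``
    is its two-norm, which equals the spectral norm of the rank-one Delta.
    """

    gamma: np.ndarray
    norm: float
    target: TargetEigenvalue
    electrode_index: int
    structure: str

    def delta(self) -> np.ndarray:
        """The full M x M perturbation matrix."""
        m = self.gamma.shape[0]
        e_k = np.zeros(m)
        e_k[self.electrode_index] = 1.0
        if self.structure == "column":
            return np.outer(self.gamma, e_k)
        return np.outer(e_k, self.gamma)


def omega_grid(size: int = 51) -> list[TargetEigenvalue]:
    """Unit-circle targets e^{i theta}, theta uniform on [0, pi].

    The upper semicircle suffices for real A (complex eigenvalues come in
    conjugate pairs) and includes the real targets +1 and -1 at the ends.
    """
    if size < 1:
        raise ValueError("omega grid size must be >= 1")
    if size == 1:
        return [TargetEigenvalue.from_angle(0.0)]
    return [TargetEigenvalue.from_angle(t) for t in np.linspace(0.0, np.pi, size)]


def _check_structure(structure: str) -> None:
    if structure not in ("row", "column"):
        raise ValueError(f"structure must be 'row' or 'column', got {structure!r}")


def _min_norm_gamma(r: np.ndarray) -> np.ndarray:
    """Minimum-norm real gamma with Re(r).gamma = -1 and Im(r).gamma = 0."""
    u, v = r.real, r.imag
    uu = u @ u
    vv = v @ v
    uv = u @ v
    det = uu * vv - uv * uv
    # Re(r) and Im(r) collinear (or omega = 0): only the real constraint binds.
    if vv <= 1e-24 * uu or det <= 1e-12 * uu * vv:
        if det > 0 and vv > 1e-24 * uu:
            logger.warning(
                "Re(r) and Im(r) nearly collinear; dropping the imaginary constraint"
            )
        if uu == 0.0:
            raise np.linalg.LinAlgError("resolvent row vanished; cannot place eigenvalue")
        return -u / uu
    # Solve B B^T [a, b]^T = [-1, 0]^T for B = [u^T; v^T].
    a = -vv / det
    b = uv / det
    return a * u + b * v


def _resolvent(A: np.ndarray, lam_star: complex) -> np.ndarray | None:
    """(A - lambda* I)^{-1}, or None when lambda* is (numerically) an eigenvalue."""
    m = A.shape[0]
    S = A - lam_star * np.eye(m)
    eigs = np.linalg.eigvals(A)
    if np.min(np.abs(eigs - lam_star)) < _EIG_TOL:
        return None
    try:
        return np.linalg.inv(S)
    except np.linalg.LinAlgError:
        logger.warning(
            "(A - lambda* I) numerically singular without an exact eigenvalue match; "
            "falling back to least-squares pseudo-inverse"
        )
        return np.linalg.pinv(S)


def min_norm_perturbation(A: np.ndarray, target: TargetEigenvalue,
                          electrode_index: int,
                          structure: str = "column") -> PerturbationResult:
    """Closed-form minimum two-norm rank-one perturbation for one electrode.

    Returns the zero perturbation when the target is already an eigenvalue
    of ``A``.
    """
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"A must be square, got shape {A.shape}")
    m = A.shape[0]
    k = int(electrode_index)
    if not (0 <= k < m):
        raise IndexError(f"electrode index {k} out of range for M={m}")
    _check_structure(structure)
    Rinv = _resolvent(A, target.value)
    if Rinv is None:
        return PerturbationResult(np.zeros(m), 0.0, target, k, structure)
    r = Rinv[k, :] if structure == "column" else Rinv[:, k]
    gamma = _min_norm_gamma(r)
    return PerturbationResult(gamma, float(np.linalg.norm(gamma)), target, k, structure)


def _min_norms_all(A: np.ndarray, targets: Sequence[TargetEigenvalue],
                   structure: str) -> np.ndarray:
    """Minimum perturbation norms for every electrode x target, vectorized.

    One resolvent inverse per target serves all M electrodes: for the column
    structure r_k is row k of the resolvent, for the row structure column k.
    """
    m = A.shape[0]
    out = np.empty((m, len(targets)))
    eigs = np.linalg.eigvals(A)
    eye = np.eye(m)
    for j, tgt in enumerate(targets):
        lam_star = tgt.value
        if np.min(np.abs(eigs - lam_star)) < _EIG_TOL:
            out[:, j] = 0.0
            continue
        S = A - lam_star * eye
        try:
            Rinv = np.linalg.inv(S)
        except np.linalg.LinAlgError:
            Rinv = np.linalg.pinv(S)
        R = Rinv if structure == "column" else Rinv.T
        u, v = R.real, R.imag
        uu = np.einsum("ij,ij->i", u, u)
        vv = np.einsum("ij,ij->i", v, v)
        uv = np.einsum("ij,ij->i", u, v)
        det = uu * vv - uv * uv
        one_constraint = (vv <= 1e-24 * uu) | (det <= 1e-12 * uu * vv)
        norms = np.empty(m)
        with np.errstate(divide="ignore", invalid="ignore"):
            # ||gamma||^2 = [ -1, 0 ] (B B^T)^{-1} [ -1, 0 ]^T = vv / det.
            norms = np.sqrt(vv / det)
            norms[one_constraint] = 1.0 / np.sqrt(uu[one_constraint])
        out[:, j] = norms
    return out


def electrode_fragility(A: np.ndarray, electrode_index: int,
                        grid: Sequence[TargetEigenvalue],
                        structure: str = "column") -> tuple[float, TargetEigenvalue]:
    """Minimum perturbation norm for one electrode over a target grid.

    Returns the minimum and the target eigenvalue achieving it.
    """
    if len(grid) == 0:
        raise ValueError("omega grid must be non-empty")
    results = [min_norm_perturbation(A, t, electrode_index, structure) for t in grid]
    best = min(results, key=lambda res: res.norm)
    return best.norm, best.target


def normalize_window(raw_norms_column: np.ndarray) -> np.ndarray:
    """Reverse-scale one window's raw norms: (max - value) / max.

    The electrode with the largest minimum perturbation norm (hardest to
    destabilize) maps to exactly 0; smaller norms map toward 1.  An all-zero
    column (every electrode trivially destabilizing) is degenerate and maps
    to all zeros with a warning.
    """
    raw = np.asarray(raw_norms_column, dtype=np.float64)
    if np.any(raw < 0):
        raise ValueError("raw perturbation norms must be non-negative")
    mx = raw.max() if raw.size else 0.0
    if mx == 0.0:
        logger.warning("all-zero raw-norm column; fragility defined as all zeros")
        return np.zeros_like(raw)
    return (mx - raw) / mx


# ---------------------------------------------------------------------------
# Sliding-window driver
# ---------------------------------------------------------------------------


def _process_window(window_data: np.ndarray, lam: float | None,
                    lambda_min: float, lambda_max: float, max_iter: int,
                    targets: Sequence[TargetEigenvalue],
                    structure: str) -> tuple[np.ndarray, float, bool, int]:
    if lam is None:
        fit = select_lambda(window_data, lambda_min, lambda_max, max_iter)
    else:
        fit = fit_window_model(window_data, lam)
    norms = _min_norms_all(fit.A, targets, structure)
    raw = norms.min(axis=1)
    return raw, fit.lam, fit.stable, fit.lambda_iterations


@dataclass
class FragilityResults:
    """Fitted fragility of an epoch: an M x W matrix plus per-window fit state.

    Produced by :meth:`FragilityModel.fit`.  ``fragility`` holds the
    reverse-scaled values in [0, 1]; ``raw_norms`` retains the un-normalized
    minimum perturbation norms so that analyses across runs (e.g. ridge-
    penalty sensitivity) are not information-lossy.
    """

    fragility: np.ndarray
    raw_norms: np.ndarray
    window_starts: np.ndarray
    window_size: int
    step: int
    lambdas: np.ndarray
    stable_flags: np.ndarray
    electrodes: list[str]
    omega_grid_size: int
    structure: str
    sampling_rate: float
    normalize: str = "window"
    soz_mask: np.ndarray | None = None
    params: dict[str, Any] = field(default_factory=dict)

    @property
    def n_electrodes(self) -> int:
        return self.fragility.shape[0]

    @property
    def n_windows(self) -> int:
        return self.fragility.shape[1]

    @property
    def window_centers(self) -> np.ndarray:
        """Window center times in seconds (for plotting)."""
        return self.window_starts + 0.5 * self.window_size / self.sampling_rate

    def estimate_soz(self, method: str = "mean", proportion: float = 0.1,
                     time_range: tuple[int, int] | None = None):
        from .soz import estimate_soz

        return estimate_soz(self, method=method, proportion=proportion,
                            time_range=time_range)

    def summary(self) -> str:
        """Human-readable overview of the fit."""
        n_unstable = int((~self.stable_flags).sum())
        mean_frag = self.fragility.mean(axis=1)
        order = np.argsort(-mean_frag)
        lines = [
            "Neural fragility results",
            "========================",
            f"electrodes:        {self.n_electrodes}",
            f"windows:           {self.n_windows} "
            f"(window={self.window_size} samples, step={self.step})",
            f"sampling rate:     {self.sampling_rate:g} Hz",
            f"perturbation:      {self.structure} structure, "
            f"{self.omega_grid_size}-point eigenvalue grid",
            f"lambda:            min {self.lambdas.min():g}, max {self.lambdas.max():g}",
            f"unstable windows:  {n_unstable} / {self.n_windows}",
            "",
            "Top electrodes by mean fragility:",
        ]
        for i in order[: min(5, self.n_electrodes)]:
            lines.append(f"  {self.electrodes[i]:<12s} {mean_frag[i]:.3f}")
        return "\n".join(lines)

    # plotting / export conveniences ---------------------------------------

    def plot_heatmap(self, group=None, ax=None):
        from .viz import plot_heatmap

        return plot_heatmap(self, group=group, ax=ax)

    def plot_distribution(self, group, band: str = "sd", ax=None):
        from .viz import plot_frag_distribution

        return plot_frag_distribution(self, group, band=band, ax=ax)

    def plot_quantile(self, group, quantiles=None, ax=None):
        from .viz import plot_frag_quantile

        return plot_frag_quantile(self, group, quantiles=quantiles, ax=ax)

    def to_hdf5(self, path) -> None:
        from .io import write_fragility

        write_fragility(self, path, format="h5")

    def to_tsv(self, path) -> None:
        from .io import write_fragility

        write_fragility(self, path, format="tsv")

    def to_frame(self):
        """Fragility matrix as a DataFrame (electrodes x window start times)."""
        import pandas as pd

        return pd.DataFrame(self.fragility, index=self.electrodes,
                            columns=np.round(self.window_starts, 9))


class FragilityModel:
    """Sliding-window neural fragility model for an iEEG epoch.

    Parameters
    ----------
    epoch : Epoch
        Input recording (preprocess first; no filtering happens here).
    window, step : int
        Window length and hop in samples.  A trailing partial window is
        dropped.
    lam : float or None
        Ridge penalty; ``None`` (default) selects it adaptively per window.
    lambda_min, lambda_max, max_iter :
        Adaptive-search range and bisection budget.
    omega_grid_size : int
        Number of target eigenvalues on the upper unit semicircle.
    structure : {'column', 'row'}
        Which rank-one structure the perturbation takes.
    normalize : {'window', 'global'}
        Reverse-scale per window (default) or against the global maximum.
    """

    def __init__(self, epoch: Epoch, window: int = 250, step: int = 125,
                 lam: float | None = None, lambda_min: float = 1e-4,
                 lambda_max: float = 10.0, max_iter: int = 20,
                 omega_grid_size: int = 51, structure: str = "column",
                 normalize: str = "window"):
        _check_structure(structure)
        if normalize not in ("window", "global"):
            raise ValueError(f"normalize must be 'window' or 'global', got {normalize!r}")
        n = epoch.n_times
        if window > n:
            raise ValueError(f"window ({window} samples) exceeds epoch length N={n}")
        if step < 1:
            raise ValueError("step must be >= 1 sample")
        if window < epoch.n_electrodes + 1:
            logger.warning(
                "window=%d samples < M+1=%d; per-window fits are underdetermined",
                window, epoch.n_electrodes + 1,
            )
        self.epoch = epoch
        self.window = int(window)
        self.step = int(step)
        self.lam = lam
        self.lambda_min = float(lambda_min)
        self.lambda_max = float(lambda_max)
        self.max_iter = int(max_iter)
        self.omega_grid_size = int(omega_grid_size)
        self.structure = structure
        self.normalize = normalize

    @property
    def n_windows(self) -> int:
        return (self.epoch.n_times - self.window) // self.step + 1

    def window_start_indices(self) -> np.ndarray:
        return np.arange(self.n_windows) * self.step

    def fit(self, parallel: bool = False, n_jobs: int = -1,
            progress: bool = False) -> FragilityResults:
        """Run the sliding-window fragility computation.

        Windows are independent, so ``parallel=True`` (joblib) returns
        bitwise-identical results to the serial path.
        """
        ep = self.epoch
        targets = omega_grid(self.omega_grid_size)
        starts = self.window_start_indices()
        windows = [ep.data[:, s: s + self.window] for s in starts]

        def run(i: int, wd: np.ndarray):
            try:
                return _process_window(wd, self.lam, self.lambda_min,
                                       self.lambda_max, self.max_iter,
                                       targets, self.structure)
            except Exception as exc:
                t = ep.start_time + starts[i] / ep.sampling_rate
                raise RuntimeError(
                    f"fragility computation failed in window {i} (start {t:.3f} s): {exc}"
                ) from exc

        if parallel and len(windows) > 1:
            outs = Parallel(n_jobs=n_jobs)(
                delayed(run)(i, wd) for i, wd in enumerate(windows)
            )
        else:
            iterator = enumerate(windows)
            if progress:
                from tqdm import tqdm

                iterator = tqdm(list(iterator), desc="fragility windows")
            outs = [run(i, wd) for i, wd in iterator]

        raw = np.column_stack([o[0] for o in outs])
        lambdas = np.array([o[1] for o in outs])
        stable = np.array([o[2] for o in outs], dtype=bool)
        if (~stable).any():
            logger.warning(
                "%d window(s) remained unstable at lambda_max; their fragility "
                "values are ill-defined and flagged", int((~stable).sum()),
            )
        if self.normalize == "window":
            frag = np.column_stack([normalize_window(raw[:, j])
                                    for j in range(raw.shape[1])])
        else:
            mx = raw.max()
            frag = (mx - raw) / mx if mx > 0 else np.zeros_like(raw)
        window_starts = ep.start_time + starts / ep.sampling_rate
        return FragilityResults(
            fragility=frag,
            raw_norms=raw,
            window_starts=window_starts,
            window_size=self.window,
            step=self.step,
            lambdas=lambdas,
            stable_flags=stable,
            electrodes=list(ep.electrodes),
            omega_grid_size=self.omega_grid_size,
            structure=self.structure,
            sampling_rate=ep.sampling_rate,
            normalize=self.normalize,
            soz_mask=ep.soz_mask() if "soz" in ep.row_data.columns else None,
            params={
                "lambda": self.lam,
                "lambda_min": self.lambda_min,
                "lambda_max": self.lambda_max,
                "max_iter": self.max_iter,
            },
        )


def calc_adj_frag(epoch: Epoch, window: int = 250, step: int = 125,
                  lam: float | None = None, omega_grid_size: int = 51,
                  structure: str = "column", parallel: bool = False,
                  progress: bool = False, **kwargs) -> FragilityResults:
    """One-call sliding-window fragility (wraps :class:`FragilityModel`)."""
    model = FragilityModel(epoch, window=window, step=step, lam=lam,
                           omega_grid_size=omega_grid_size,
                           structure=structure, **kwargs)
    return model.fit(parallel=parallel, progress=progress)
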