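"""Essential dynamics: iterative superposition, PCA, projections, surfaces.

The coordinate covariance C = <(x - <x>)(x - <x>)^T> of an ensemble that
has been iteratively superposed onto its own converging mean captures the
internal fluctuations; its leading eigenvectors are the collective modes
(for four-way junctions, the interduplex scissor twist J_twist and the arm
roll J_roll dominate).  Superposition removes six rigid-body degrees of
freedom, so the six smallest-magnitude eigenvalues are discarded.
Projections p_i(t) = nu_i . (x(t) - <x>) have variance lambda_i, and 2-D
histograms of two projections Boltzmann-invert to free-energy surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kT_kcal
from .geometry import _kabsch

#: backbone atom names used for junction PCA (sugar-phosphate trace)
BACKBONE_ATOMS = ("P", "O5'", "C5'", "C4'", "C3'", "O3'")


@dataclass
class AlignedEnsemble:
    """Frames superposed on their converged mean structure.

    ``frames`` is (n_frames, n_atoms, 3); ``mean`` is (n_atoms, 3).
    ``history`` records the mean-shift RMSD per superposition iteration.
    """

    frames: np.ndarray
    mean: np.ndarray
    history: list[float] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


def _align_one(frame: np.ndarray, ref: np.ndarray) -> np.ndarray:
    R, t, _ = _kabsch(frame, ref)
    return frame @ R.T + t


def iterative_superposition(
    ensemble: np.ndarray,
    *,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> AlignedEnsemble:
    """Align all frames onto an iteratively refined mean structure.

    All frames are first superposed onto frame 0, the mean is computed and
    set as the new reference, and the cycle repeats until the RMSD between
    successive means drops below ``tol`` (default 1e-4 A).
    """
    frames = np.asarray(ensemble, float)
    if frames.ndim != 3 or frames.shape[2] != 3:
        raise ValueError("ensemble must be (n_frames, n_atoms, 3)")
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    ref = frames[0]
    history: list[float] = []
    for _ in range(max_iter):
        aligned = np.array([_align_one(f, ref) for f in frames])
        mean = aligned.mean(axis=0)
        shift = float(np.sqrt(((mean - ref) ** 2).sum() / mean.shape[0]))
        history.append(shift)
        ref = mean
        if shift < tol:
            return AlignedEnsemble(aligned, mean, history)
    raise RuntimeError(
        f"superposition did not converge in {max_iter} iterations; "
        f"history={history[-5:]}"
    )


@dataclass
class ModeSet:
    """Eigenvalues (A^2, descending) and unit eigenvectors of the covariance.

    Six smallest-magnitude eigenvalues (rigid-body remnants left by the
    superposition) are discarded; ``rigid_mass`` records their summed
    magnitude for bookkeeping.  ``mean`` is the (n_atoms, 3) reference.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # (n_modes, 3*n_atoms), rows unit-norm
    mean: np.ndarray
    n_discarded_zero_modes: int = 6
    rigid_mass: float = 0.0
    rank_warning: bool = False

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())


def essential_modes(aligned: AlignedEnsemble, *, n_discard: int = 6) -> ModeSet:
    """Diagonalize the coordinate covariance and drop rigid-body modes."""
    n, m = aligned.n_frames, aligned.n_atoms
    if n <= n_discard:
        raise ValueError(f"need more than {n_discard} frames, got {n}")
    X = aligned.frames.reshape(n, 3 * m) - aligned.mean.reshape(1, 3 * m)
    C = (X.T @ X) / n  # ensemble average, matching <...> in the covariance
    w, V = np.linalg.eigh(C)
    order = np.argsort(np.abs(w))
    rigid = order[:n_discard]
    keep = order[n_discard:]
    rigid_mass = float(np.abs(w[rigid]).sum())
    keep = keep[np.argsort(w[keep])[::-1]]
    eigvals = w[keep]
    vecs = V[:, keep].T.copy()
    # reproducible sign: largest-magnitude component positive
    for row in vecs:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    rank_warning = n < 3 * m
    if eigvals.size and rigid_mass > 1e-6 * max(np.abs(eigvals[0]), 1e-300):
        rank_warning = True
    return ModeSet(
        eigenvalues=eigvals,
        eigenvectors=vecs,
        mean=aligned.mean,
        n_discarded_zero_modes=n_discard,
        rigid_mass=rigid_mass,
        rank_warning=rank_warning,
    )


def align_modes(modeset: ModeSet, reference_mean: np.ndarray) -> ModeSet:
    """Rotate a ModeSet into the orientation of a reference structure.

    Superposition fixes only the internal geometry; the converged mean (and
    with it every eigenvector) sits in an arbitrary global orientation.  To
    compare recovered modes against externally defined vectors, superpose
    the mode mean onto the reference structure and co-rotate the
    eigenvectors atom-wise.
    """
    from .geometry import _kabsch

    ref = np.asarray(reference_mean, float)
    R, t, _ = _kabsch(modeset.mean, ref)
    new_mean = modeset.mean @ R.T + t
    m = modeset.mean.shape[0]
    vecs = modeset.eigenvectors.reshape(-1, m, 3) @ R.T
    return ModeSet(
        eigenvalues=modeset.eigenvalues.copy(),
        eigenvectors=vecs.reshape(-1, 3 * m),
        mean=new_mean,
        n_discarded_zero_modes=modeset.n_discarded_zero_modes,
        rigid_mass=modeset.rigid_mass,
        rank_warning=modeset.rank_warning,
    )


def project(
    frames: np.ndarray,
    mode: np.ndarray,
    mean: np.ndarray,
    *,
    check_alignment: bool = True,
    cog_tol: float = 1e-6,
) -> np.ndarray:
    """Projection p_i(t) = nu_i . (x(t) - <x>) for each frame (in A)."""
    frames = np.atleast_3d(np.asarray(frames, float))
    mean = np.asarray(mean, float)
    if check_alignment:
        cog = frames.mean(axis=1) - mean.mean(axis=0)
        if np.abs(cog).max() > max(cog_tol, 1e-6 * np.abs(mean).max()):
            raise ValueError(
                "frames appear unaligned to the mean (center-of-geometry "
                f"offset {np.abs(cog).max():.3g} A); superpose first"
            )
    dev = frames.reshape(frames.shape[0], -1) - mean.reshape(1, -1)
    return dev @ np.asarray(mode, float)


def backproject(p, mode: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Cartesian structure(s) x* = p nu + <x> along one mode."""
    mean_flat = np.asarray(mean, float).reshape(-1)
    p_arr = np.atleast_1d(np.asarray(p, float))
    coords = p_arr[:, None] * np.asarray(mode, float)[None, :] + mean_flat
    out = coords.reshape(len(p_arr), -1, 3)
    return out[0] if np.isscalar(p) or np.ndim(p) == 0 else out


@dataclass
class ProjectionSurface:
    """Free-energy surface over a 2-D projection histogram.

    ``free_energy`` is -kT ln(n_ij / n_max) with empty bins set to NaN
    (flagged, never zero); the most populated bin defines F = 0.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    free_energy: np.ndarray
    temperature: float

    @property
    def bin_area(self) -> float:
        return float(
            (self.x_edges[1] - self.x_edges[0]) * (self.y_edges[1] - self.y_edges[0])
        )


def projection_surface(
    p1: np.ndarray,
    p2: np.ndarray,
    *,
    bin_edge: float = 0.2,
    temperature: float = DEFAULT_TEMPERATURE,
) -> ProjectionSurface:
    """2-D histogram of two projections with Boltzmann-inverted free energy.

    Default bins are 0.2 x 0.2 A (area 0.04 A^2); F is referenced to the
    most populated bin.
    """
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    if p1.shape != p2.shape:
        raise ValueError("projection series must have equal length")

    def edges(v: np.ndarray) -> np.ndarray:
        lo = np.floor(v.min() / bin_edge) * bin_edge
        hi = np.ceil(v.max() / bin_edge) * bin_edge
        if hi <= lo:
            hi = lo + bin_edge
        return np.arange(lo, hi + bin_edge / 2, bin_edge)

    xe, ye = edges(p1), edges(p2)
    counts, xe, ye = np.histogram2d(p1, p2, bins=(xe, ye))
    n_max = counts.max()
    if (counts > 0).sum() == 1:
        import warnings

        warnings.warn("all mass in a single bin: degenerate surface", stacklevel=2)
    with np.errstate(divide="ignore"):
        F = np.where(counts > 0, -kT_kcal(temperature) * np.log(counts / n_max), np.nan)
    return ProjectionSurface(xe, ye, counts, F, temperature)
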