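"""Seed-deterministic synthetic ensembles emulating junction MD statistics.

No MD trajectories ship with the package; every analysis stage is instead
exercised on generated data whose statistical structure matches what the
analyses assume: (a) AR(1)-correlated Gaussian base-pair step parameters
with prescribed per-step 6x6 stiffness, optionally realized as full duplex
coordinates; (b) backbone coordinate ensembles dominated by a few planted
collective modes under per-frame rigid motions; (c) per-bin ABF force
statistics drawn around the gradient of a known 1-D potential; (d) donor
photon-count decays Poisson-sampled from the two-isomer FRET model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kT_kcal
from .fret import DecayCurve, FretModel, donor_decay
from .geometry import (
    IDENTITY_FRAME,
    StepParams,
    StepSeries,
    rebuild_helix,
    standard_base_atoms,
)
from .sampling import DEFAULT_BINS_PER_WINDOW, DEFAULT_WINDOWS, WindowForceData
from .schema import StepLabel, JunctionTopology

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _spec_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def provenance(seed: int, **spec_fields) -> dict:
    """Provenance block (spec hash + seed) embedded in generator outputs."""
    return {"seed": int(seed), "spec_hash": _spec_hash(spec_fields)}


# ---------------------------------------------------------------------------
# (a) step-parameter ensembles


def _ar1_gaussian(
    rng: np.random.Generator,
    mean: np.ndarray,
    cov: np.ndarray,
    phi: float,
    n: int,
) -> np.ndarray:
    """Stationary AR(1) draws with marginal N(mean, cov)."""
    if not -1.0 < phi < 1.0:
        raise ValueError("AR(1) coefficient must satisfy |phi| < 1")
    L = np.linalg.cholesky(cov)
    d = mean.size
    x = np.empty((n, d))
    z = rng.standard_normal((n, d))
    x[0] = L @ z[0]
    innov = np.sqrt(1.0 - phi**2)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + innov * (L @ z[t])
    return x + mean


@dataclass
class StepEnsembleSpec:
    """Per-step generating parameters for a synthetic duplex ensemble.

    ``stiffness`` entries are 6x6 F_h matrices (kcal/mol units); the
    generating covariance is k_B T F^-1.  Alternatively pass covariances
    directly via ``covariance``.  ``phi`` is the per-step AR(1) coefficient
    (0 = white noise).
    """

    sequence: str = "CGCAATCCTGAGCACG"
    n_frames: int = 2000
    sampling_interval: float = 10.0  # ps
    temperature: float = DEFAULT_TEMPERATURE
    mean: Mapping[int, Sequence[float]] | None = None  # physical step -> 6
    stiffness: Mapping[int, np.ndarray] | None = None
    covariance: Mapping[int, np.ndarray] | None = None
    phi: float | Mapping[int, float] = 0.0

    def step_cov(self, phys: int) -> np.ndarray:
        if self.covariance is not None and phys in self.covariance:
            return np.asarray(self.covariance[phys], float)
        if self.stiffness is not None and phys in self.stiffness:
            F = np.asarray(self.stiffness[phys], float)
            return kT_kcal(self.temperature) * np.linalg.inv(F)
        # default: a loose, diagonally dominant B-DNA-like covariance
        return np.diag([0.16, 0.36, 0.09, 9.0, 25.0, 16.0])

    def step_mean(self, phys: int) -> np.ndarray:
        if self.mean is not None and phys in self.mean:
            return np.asarray(self.mean[phys], float)
        return np.array([0.0, 0.0, 3.4, 0.0, 0.0, 36.0])

    def step_phi(self, phys: int) -> float:
        if isinstance(self.phi, Mapping):
            return float(self.phi.get(phys, 0.0))
        return float(self.phi)


def gen_step_series(
    spec: StepEnsembleSpec, seed: int, *, topology_code: str = "d", core: str = "1"
) -> dict[int, StepSeries]:
    """AR(1) Gaussian step-parameter series per physical step of the duplex."""
    rng = np.random.default_rng(seed)
    n_steps = len(spec.sequence) - 1
    out: dict[int, StepSeries] = {}
    for phys in range(1, n_steps + 1):
        cov = spec.step_cov(phys)
        w = np.linalg.eigvalsh((cov + cov.T) / 2)
        if w.min() <= 0:
            raise ValueError(f"step {phys}: generating covariance is not SPD")
        vals = _ar1_gaussian(
            rng, spec.step_mean(phys), cov, spec.step_phi(phys), spec.n_frames
        )
        # label by analyzed-step index when inside the analyzed range
        idx = phys - 3
        label = StepLabel(
            topology_code, core, 1, 1, idx if 1 <= idx <= 9 else min(max(idx, 1), 9)
        )
        out[phys] = StepSeries(
            label, vals, spec.sampling_interval,
            sequence=spec.sequence[phys - 1 : phys + 1],
        )
    return out


@dataclass
class SyntheticEnsemble:
    """In-memory coordinate ensemble with (strand, residue, atom) indexing."""

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    atoms: list[tuple[str, int, str]]  # (strand, 1-based residue, atom name)
    sequence_by_strand: dict[str, str]
    provenance: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def base_atoms(self, frame: int, strand: str, position: int) -> dict[str, np.ndarray]:
        out = {}
        for k, (s, p, name) in enumerate(self.atoms):
            if s == strand and p == position:
                out[name] = self.coords[frame, k]
        return out


def duplex_topology(sequence: str, *, name: str = "d1") -> JunctionTopology:
    """Two-strand B-duplex topology for a reading sequence (strands R/S)."""
    n = len(sequence)
    comp = "".join(_COMPLEMENT[b] for b in sequence)[::-1]
    doc = {
        "name": name,
        "topology_code": "d",
        "strands": {"R": sequence, "S": comp},
        "pairing_blocks": [
            {"strand_a": "R", "from_a": 1, "to_a": n, "strand_b": "S", "from_b": n}
        ],
        "helices": {"1,1": {"strand": "R", "from": 1, "to": n}},
    }
    return JunctionTopology.from_dict(doc)


def gen_step_ensemble(
    spec: StepEnsembleSpec,
    seed: int,
    *,
    rebuild_coordinates: bool = False,
    rigid_motions: bool = False,
) -> tuple[dict[int, StepSeries], SyntheticEnsemble | None]:
    """Step series per physical step, optionally realized as 3-D coordinates.

    When ``rebuild_coordinates`` is set, each frame's base-pair frames are
    rebuilt by chaining the drawn step parameters from the identity frame
    and idealized base atoms are placed in them (reading base in the pair
    frame, complement flipped 180 deg about x), yielding an ensemble whose
    re-extracted step parameters equal the drawn ones.
    """
    series = gen_step_series(spec, seed)
    if not rebuild_coordinates:
        return series, None
    rng = np.random.default_rng(seed + 1)
    seq = spec.sequence
    n_bp = len(seq)
    atom_index: list[tuple[str, int, str]] = []
    templates: list[tuple[str, int, np.ndarray, bool]] = []
    for j in range(1, n_bp + 1):
        b = seq[j - 1]
        for name, xyz in standard_base_atoms(b).items():
            atom_index.append(("R", j, name))
            templates.append((b, j, xyz, False))
    for j in range(1, n_bp + 1):
        b = _COMPLEMENT[seq[j - 1]]
        comp_pos = n_bp + 1 - j  # complement residue index on strand S
        for name, xyz in standard_base_atoms(b).items():
            atom_index.append(("S", comp_pos, name))
            templates.append((b, j, xyz, True))
    n_frames = spec.n_frames
    coords = np.empty((n_frames, len(templates), 3))
    flip = np.diag([1.0, -1.0, -1.0])
    for f in range(n_frames):
        params = [StepParams.from_array(series[p].values[f]) for p in sorted(series)]
        frames = rebuild_helix(IDENTITY_FRAME, params)
        for k, (_, j, xyz, flipped) in enumerate(templates):
            fr = frames[j - 1]
            R = fr.rotation @ flip if flipped else fr.rotation
            coords[f, k] = R @ xyz + fr.origin
        if rigid_motions:
            from scipy.spatial.transform import Rotation

            Q = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(0.0, 20.0, 3)
            coords[f] = coords[f] @ Q.T + t
    comp_seq = "".join(_COMPLEMENT[b] for b in seq)[::-1]
    ens = SyntheticEnsemble(
        coords,
        atom_index,
        {"R": seq, "S": comp_seq},
        provenance(seed, kind="step_ensemble", sequence=seq, n_frames=n_frames),
    )
    return series, ens


# ---------------------------------------------------------------------------
# (b) planted-mode coordinate ensembles


@dataclass
class ModeEnsembleSpec:
    """Planted collective modes on top of a helical mean structure."""

    n_atoms: int = 60
    n_frames: int = 2000
    mode_variances: tuple[float, ...] = (9.0, 1.0)  # A^2
    noise_sigma2: float = 0.01  # isotropic per-coordinate variance, A^2
    phi: float = 0.0
    rigid_motions: bool = True


def _helical_mean(n_atoms: int) -> np.ndarray:
    """A B-DNA-like helical curve used as the mean structure."""
    t = np.arange(n_atoms)
    ang = 2 * np.pi * t / 10.0
    return np.column_stack([9.0 * np.cos(ang), 9.0 * np.sin(ang), 3.4 * t / 1.0])


def _rigid_body_basis(mean: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 6 rigid-body directions at a structure."""
    n = mean.shape[0]
    basis = []
    for ax in range(3):
        v = np.zeros((n, 3))
        v[:, ax] = 1.0
        basis.append(v.reshape(-1))
    centered = mean - mean.mean(axis=0)
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        basis.append(np.cross(centered, e).reshape(-1))
    B = np.array(basis).T
    Q, _ = np.linalg.qr(B)
    return Q[:, :6]


def gen_mode_ensemble(spec: ModeEnsembleSpec, seed: int):
    """Coordinates mean + sum_k a_k(t) nu_k + noise, with rigid motions.

    Planted mode vectors are random unit vectors orthogonalized against the
    rigid-body space of the mean (so superposition cannot absorb them) and
    against each other.  Returns (frames, mean, modes, provenance) where
    ``modes`` rows are the planted unit vectors.
    """
    rng = np.random.default_rng(seed)
    n, m = spec.n_frames, spec.n_atoms
    dim = 3 * m
    if len(spec.mode_variances) > dim - 6:
        raise ValueError("more planted modes than internal degrees of freedom")
    mean = _helical_mean(m)
    rigid = _rigid_body_basis(mean)
    modes = []
    for _ in spec.mode_variances:
        v = rng.standard_normal(dim)
        v -= rigid @ (rigid.T @ v)
        for u in modes:
            v -= (u @ v) * u
        v /= np.linalg.norm(v)
        modes.append(v)
    modes = np.array(modes)
    if len(spec.mode_variances):
        amps = np.column_stack(
            [
                _ar1_gaussian(rng, np.zeros(1), np.array([[s2]]), spec.phi, n).ravel()
                for s2 in spec.mode_variances
            ]
        )
        planted = amps @ modes
    else:
        planted = 0.0
    frames = (
        mean.reshape(1, dim)
        + planted
        + rng.normal(0.0, np.sqrt(spec.noise_sigma2), (n, dim))
    ).reshape(n, m, 3)
    if spec.rigid_motions:
        from scipy.spatial.transform import Rotation

        for f in range(n):
            Q = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(0.0, 30.0, 3)
            frames[f] = frames[f] @ Q.T + t
    return frames, mean, modes, provenance(seed, kind="mode_ensemble", **asdict(spec))


# ---------------------------------------------------------------------------
# (c) ABF force samples


@dataclass
class AbfForceSpec:
    """Force-bin statistics around a known 1-D potential A(xi)."""

    potential: Callable[[np.ndarray], np.ndarray] = None  # type: ignore[assignment]
    grad: Callable[[np.ndarray], np.ndarray] | None = None
    windows: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS
    bins_per_window: int = DEFAULT_BINS_PER_WINDOW
    force_sigma: float = 0.5  # kcal/mol/A
    tau: float = 0.0  # correlation length, samples
    n_samples_per_bin: int = 500

    def __post_init__(self) -> None:
        if self.potential is None:
            self.potential = lambda x: 0.5 * x**2
            self.grad = lambda x: x

    def gradient(self, x: np.ndarray) -> np.ndarray:
        if self.grad is not None:
            return self.grad(x)
        h = 1e-6
        return (self.potential(x + h) - self.potential(x - h)) / (2 * h)


def gen_abf_forces(spec: AbfForceSpec, seed: int) -> list[WindowForceData]:
    """Per-bin mean forces -dA/dxi plus noise of the mean-force estimator.

    The sampled mean force in a bin of K correlated samples has standard
    error sigma sqrt((1 + 2 tau) / K); bins record sigma^2, K and tau so the
    ABF error bound can be evaluated downstream.
    """
    rng = np.random.default_rng(seed)
    out = []
    for wi, (a, b) in enumerate(spec.windows):
        edges = np.linspace(a, b, spec.bins_per_window + 1)
        centers = (edges[:-1] + edges[1:]) / 2.0
        true_force = -spec.gradient(centers)
        K = float(spec.n_samples_per_bin)
        se = spec.force_sigma * np.sqrt((1.0 + 2.0 * spec.tau) / K)
        mean_force = true_force + rng.normal(0.0, se, centers.shape)
        out.append(
            WindowForceData(
                (a, b),
                centers,
                mean_force,
                np.full_like(centers, spec.force_sigma**2),
                np.full_like(centers, K),
                np.full_like(centers, spec.tau),
                window_id=f"w{wi}",
            )
        )
    return out


# ---------------------------------------------------------------------------
# (d) FRET decays


@dataclass
class DecaySpec:
    """Synthetic donor-decay acquisition parameters."""

    model: FretModel = field(default_factory=FretModel)
    t_max: float = 50.0  # ns
    n_channels: int = 512
    total_counts: float = 1e6


def gen_decay(spec: DecaySpec, seed: int) -> DecayCurve:
    """Poisson-sampled donor decay on a uniform time grid."""
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, spec.t_max, spec.n_channels)
    ideal = donor_decay(spec.model, times)
    expected = ideal / ideal.sum() * spec.total_counts
    counts = rng.poisson(expected).astype(float)
    return DecayCurve(times, counts)
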