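"""Base reference frames and base-pair step parameters (CEHS/3DNA scheme).

A base frame is a right-handed orthonormal triad attached to a base by
least-squares superposition of the standard-geometry ring onto the observed
ring atoms.  Two paired bases yield a base-pair frame (the geodesic
mid-frame after flipping the complementary base 180 deg about its x-axis),
and two consecutive base-pair frames yield the six step parameters
shift/slide/rise (Angstrom) and tilt/roll/twist (degrees) via the mid-step
frame construction: both pair frames are rotated halfway about the
roll-tilt hinge axis (z1 x z2) onto a common mid z-axis; twist is the angle
between the x-axes about that axis, the bending angle decomposes onto the
mid x (tilt) and mid y (roll), and the origin displacement is expressed in
mid-frame coordinates.

``rebuild_step`` is the exact inverse and is what the synthetic-ensemble
generator uses to realize prescribed step-parameter time series as 3-D
coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .schema import JunctionTopology, StepLabel, analyzed_steps

_FLIP_X = np.diag([1.0, -1.0, -1.0])  # 180 deg about x: pairing convention


class FrameFitError(ValueError):
    """Base-frame fitting failed (missing atoms or degenerate geometry)."""


# ---------------------------------------------------------------------------
# standard base geometry


def _load_standard_bases() -> dict:
    path = Path(__file__).parent / "data" / "standard_bases.json"
    with open(path) as fh:
        return json.load(fh)


_STANDARD = _load_standard_bases()
RING_ATOMS: dict[str, list[str]] = _STANDARD["ring_atoms"]
STANDARD_COORDS: dict[str, dict[str, list[float]]] = _STANDARD["coordinates"]


def standard_base_atoms(base_type: str, *, ring_only: bool = False) -> dict[str, np.ndarray]:
    """Standard-frame coordinates for one base type (A, C, G or T)."""
    if base_type not in STANDARD_COORDS:
        raise KeyError(f"unknown base type {base_type!r}")
    names = RING_ATOMS[base_type] if ring_only else STANDARD_COORDS[base_type]
    return {n: np.asarray(STANDARD_COORDS[base_type][n], float) for n in names}


# ---------------------------------------------------------------------------
# frames


@dataclass(frozen=True)
class OrthFrame:
    """Right-handed orthonormal rotation (columns = x, y, z axes) + origin (A)."""

    rotation: np.ndarray
    origin: np.ndarray
    fit_rmsd: float = 0.0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        o = np.asarray(self.origin, float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "origin", o)
        if R.shape != (3, 3) or o.shape != (3,):
            raise ValueError("rotation must be 3x3 and origin a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation is left-handed (det < 0)")

    @property
    def x(self) -> np.ndarray:
        return self.rotation[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.rotation[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.rotation[:, 2]

    def transform(self, local: np.ndarray) -> np.ndarray:
        """Map local-frame coordinates into the lab frame."""
        return np.asarray(local, float) @ self.rotation.T + self.origin

    def flipped(self) -> "OrthFrame":
        """Frame rotated 180 deg about its own x-axis (pairing convention)."""
        return OrthFrame(self.rotation @ _FLIP_X, self.origin, self.fit_rmsd)


IDENTITY_FRAME = OrthFrame(np.eye(3), np.zeros(3))


def _kabsch(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid motion R, t with R@moving_i + t ~= target_i."""
    mc, tc = moving.mean(axis=0), target.mean(axis=0)
    H = (moving - mc).T @ (target - tc)
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    resid = (moving - mc) @ R.T + tc - target
    rmsd = float(np.sqrt((resid**2).sum() / len(moving)))
    return R, t, rmsd


def fit_base_frame(
    atom_coords: Mapping[str, Sequence[float]],
    base_type: str,
    *,
    include_c1p: bool = False,
) -> OrthFrame:
    """Fit the standard base reference frame to observed base-ring atoms.

    The embedded standard ring is rigidly superposed (Kabsch least squares)
    onto the observed ring; the frame carried by the standard geometry is
    returned transformed by that rigid motion, with the fit RMSD recorded.
    """
    names = list(RING_ATOMS[base_type])
    if include_c1p:
        names.append("C1'")
    missing = [n for n in names if n not in atom_coords]
    if missing:
        raise FrameFitError(
            f"base {base_type}: missing ring atom(s) {', '.join(missing)}"
        )
    obs = np.array([atom_coords[n] for n in names], float)
    std = np.array([STANDARD_COORDS[base_type][n] for n in names], float)
    spread = np.linalg.svd(obs - obs.mean(axis=0), compute_uv=False)
    if spread[1] < 1e-6:
        raise FrameFitError(f"base {base_type}: degenerate (collinear) ring")
    R, t, rmsd = _kabsch(std, obs)
    return OrthFrame(R, t, fit_rmsd=rmsd)


def pair_frame(frame_a: OrthFrame, frame_b: OrthFrame) -> OrthFrame:
    """Base-pair frame: geodesic mid-rotation of the two base frames.

    ``frame_b`` must already be in the pairing convention (the complementary
    base's fitted frame flipped 180 deg about its x-axis; see
    :meth:`OrthFrame.flipped`).  The pair origin is the midpoint of the two
    origins.  If the z-axes differ by more than 90 deg the pair is flagged
    as broken via a warning but still computed.
    """
    if frame_a.z @ frame_b.z < 0:
        import warnings

        warnings.warn("pair frames more than 90 deg apart in z (broken pair)",
                      stacklevel=2)
    rel = Rotation.from_matrix(frame_a.rotation.T @ frame_b.rotation)
    half = Rotation.from_rotvec(rel.as_rotvec() / 2.0)
    R = frame_a.rotation @ half.as_matrix()
    o = (frame_a.origin + frame_b.origin) / 2.0
    return OrthFrame(R, o)


def base_pair_frame(frame_read: OrthFrame, frame_comp: OrthFrame) -> OrthFrame:
    """Pair frame from the two as-fitted base frames (flips the complement)."""
    return pair_frame(frame_read, frame_comp.flipped())


# ---------------------------------------------------------------------------
# step parameters


@dataclass(frozen=True)
class StepParams:
    """Six rigid-body step parameters: shift/slide/rise (A), tilt/roll/twist (deg)."""

    shift: float
    slide: float
    rise: float
    tilt: float
    roll: float
    twist: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.shift, self.slide, self.rise, self.tilt, self.roll, self.twist]
        )

    @classmethod
    def from_array(cls, v: Sequence[float]) -> "StepParams":
        return cls(*(float(x) for x in v))


PARAM_NAMES = ("shift", "slide", "rise", "tilt", "roll", "twist")

IDEAL_B_STEP = StepParams(0.0, 0.0, 3.4, 0.0, 0.0, 36.0)


def _rot(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    return Rotation.from_rotvec(axis * angle_rad).as_matrix()


def _signed_angle(u: np.ndarray, v: np.ndarray, about: np.ndarray) -> float:
    return float(np.arctan2(np.cross(u, v) @ about, u @ v))


def step_parameters(pair_frame_1: OrthFrame, pair_frame_2: OrthFrame) -> StepParams:
    """Six step parameters between consecutive base-pair frames (5'->3')."""
    R1, R2 = pair_frame_1.rotation, pair_frame_2.rotation
    z1, z2 = R1[:, 2], R2[:, 2]
    cross = np.cross(z1, z2)
    norm = np.linalg.norm(cross)
    gamma = float(np.arctan2(norm, z1 @ z2))
    if norm > 1e-12:
        hinge = cross / norm
        R1p = _rot(hinge, gamma / 2.0) @ R1
        R2p = _rot(hinge, -gamma / 2.0) @ R2
    else:
        hinge = None
        R1p, R2p = R1, R2
    zm = R1p[:, 2]
    twist = _signed_angle(R1p[:, 0], R2p[:, 0], zm)
    Rm = _rot(zm, twist / 2.0) @ R1p
    if hinge is not None:
        tilt = gamma * (hinge @ Rm[:, 0])
        roll = gamma * (hinge @ Rm[:, 1])
    else:
        tilt = roll = 0.0
    disp = Rm.T @ (pair_frame_2.origin - pair_frame_1.origin)
    deg = 180.0 / np.pi
    return StepParams(
        shift=float(disp[0]),
        slide=float(disp[1]),
        rise=float(disp[2]),
        tilt=tilt * deg,
        roll=roll * deg,
        twist=twist * deg,
    )


def rebuild_step(start: OrthFrame, params: StepParams) -> OrthFrame:
    """Successor frame such that ``step_parameters(start, result) == params``."""
    rad = np.pi / 180.0
    tilt, roll, omega = params.tilt * rad, params.roll * rad, params.twist * rad
    gamma = float(np.hypot(tilt, roll))
    R1 = start.rotation
    if gamma > 1e-14:
        phi = float(np.arctan2(tilt, roll))
        hinge = R1 @ np.array(
            [np.sin(phi - omega / 2.0), np.cos(phi - omega / 2.0), 0.0]
        )
        R1p = _rot(hinge, gamma / 2.0) @ R1
        zm = R1p[:, 2]
        R2 = _rot(hinge, gamma / 2.0) @ _rot(zm, omega) @ R1p
    else:
        zm = R1[:, 2]
        R1p = R1
        R2 = _rot(zm, omega) @ R1
    Rm = _rot(zm, omega / 2.0) @ R1p
    o2 = start.origin + Rm @ np.array([params.shift, params.slide, params.rise])
    return OrthFrame(R2, o2)


def rebuild_helix(start: OrthFrame, params: Iterable[StepParams]) -> list[OrthFrame]:
    """Chain of base-pair frames from a start frame and per-step parameters."""
    frames = [start]
    for p in params:
        frames.append(rebuild_step(frames[-1], p))
    return frames


# ---------------------------------------------------------------------------
# time series


@dataclass
class StepSeries:
    """Uniformly sampled time series of the six parameters for one step."""

    label: StepLabel
    values: np.ndarray  # (n_frames, 6) in PARAM_NAMES order
    sampling_interval: float = 10.0  # ps
    sequence: str = ""  # dinucleotide context, e.g. "CT"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if self.values.shape[1] != 6:
            raise ValueError("StepSeries values must be (n, 6)")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.sampling_interval

    def mean(self) -> StepParams:
        return StepParams.from_array(self.values.mean(axis=0))


def extract_step_series(
    ensemble: "StructureEnsemble",
    topology: JunctionTopology,
    isomer: int,
    *,
    excluded_terminal_steps: int = 3,
    sampling_interval: float = 10.0,
) -> dict[str, StepSeries]:
    """Per-step parameter time series for both helices of one isomer.

    ``ensemble`` is any object exposing ``n_frames`` and
    ``base_atoms(frame, strand, position) -> {atom: xyz}`` (see
    :class:`junctionmd.io.StructureEnsemble`).  Terminal steps are excluded
    per the junction bookkeeping and series are keyed by rendered label.
    """
    out: dict[str, StepSeries] = {}
    for helix in (1, 2):
        if (isomer, helix) not in topology.helices:
            continue
        pairs = topology.helix_pairs(isomer, helix)
        seq = topology.helix_sequence(isomer, helix)
        n_bp = len(pairs)
        steps = analyzed_steps(n_bp, excluded_terminal_steps)
        per_step = {idx: [] for _, idx in steps}
        for f in range(ensemble.n_frames):
            bp_frames = []
            for (rs, rp), (cs, cp) in pairs:
                fr = fit_base_frame(
                    ensemble.base_atoms(f, rs, rp), topology.strands[rs][rp - 1]
                )
                fc = fit_base_frame(
                    ensemble.base_atoms(f, cs, cp), topology.strands[cs][cp - 1]
                )
                bp_frames.append(base_pair_frame(fr, fc))
            for phys, idx in steps:
                p = step_parameters(bp_frames[phys - 1], bp_frames[phys])
                per_step[idx].append(p.as_array())
        for phys, idx in steps:
            label = StepLabel(
                topology.topology_code, topology.name_core, isomer, helix, idx
            )
            out[label.render()] = StepSeries(
                label,
                np.array(per_step[idx]),
                sampling_interval,
                sequence=seq[phys - 1 : phys + 1],
            )
    return out
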