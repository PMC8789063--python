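"""Eigenvector-projection colvar, ABF-style PMF assembly and error analysis.

The collective variable is the projection of a structure's best-fit
superposed deviation from a reference onto a fixed unit vector in R^{3n}
(in practice a PCA eigenvector, e.g. the junction twist mode).  The PMF
A(xi) is recovered by integrating per-bin average forces collected in
overlapping windows; windows are stitched with least-squares constant
offsets on their overlaps and gauged so the global minimum is zero.  The
standard-error bound for an ABF free-energy difference over [xi_a, xi_b] is

    SD[dA] ~ (xi_b - xi_a) * sigma / sqrt(K) * sqrt(1 + 2 tau)

with sigma^2 the force variance, K the number of force samples and tau the
force correlation length (in samples).  Correlation lengths come from
Flyvbjerg-Petersen blocking analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .geometry import _kabsch

#: default window layout along the junction-twist colvar (A): five
#: overlapping windows of 15 force bins each covering [-5, 10]
DEFAULT_WINDOWS = ((-5.0, -1.0), (-2.0, 3.0), (1.0, 6.0), (4.0, 8.0), (6.0, 10.0))
DEFAULT_BINS_PER_WINDOW = 15

#: affine calibration between the colvar (A) and the junction twist angle
#: (degrees): -5 A <-> -90 deg, +10 A <-> +90 deg
COLVAR_TO_JTWIST = (12.0, -30.0)  # degrees = slope * A + intercept


def colvar_to_jtwist(xi, slope: float = COLVAR_TO_JTWIST[0],
                     intercept: float = COLVAR_TO_JTWIST[1]):
    """Map colvar displacement (A) to junction twist (degrees)."""
    return slope * np.asarray(xi, float) + intercept


# ---------------------------------------------------------------------------
# colvar


@dataclass
class ColvarDefinition:
    """Reference coordinates plus the unit projection vector."""

    reference: np.ndarray  # (n_atoms, 3)
    vector: np.ndarray  # (3*n_atoms,) unit norm

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, float)
        self.vector = np.asarray(self.vector, float)
        if self.vector.shape != (self.reference.size,):
            raise ValueError("vector length must equal 3 * n_atoms")
        n = np.linalg.norm(self.vector)
        if abs(n - 1.0) > 1e-10:
            raise ValueError(f"projection vector must be unit norm, got {n}")


def eval_colvar(frame: np.ndarray, colvar: ColvarDefinition) -> float:
    """Projection of the optimally superposed deviation onto the mode vector.

    Centers of geometry of frame and reference are removed, the frame is
    optimally rotated onto the reference, and the remaining deviation is
    projected onto the unit vector.
    """
    frame = np.asarray(frame, float)
    if frame.shape != colvar.reference.shape:
        raise ValueError(
            f"frame has {frame.shape[0]} atoms, reference "
            f"{colvar.reference.shape[0]}"
        )
    ref = colvar.reference - colvar.reference.mean(axis=0)
    mov = frame - frame.mean(axis=0)
    R, _, _ = _kabsch(mov, ref)
    dev = mov @ R.T - ref
    return float(dev.reshape(-1) @ colvar.vector)


# ---------------------------------------------------------------------------
# window force data and PMF integration


@dataclass
class WindowForceData:
    """Per-bin mean-force statistics for one sampling window."""

    interval: tuple[float, float]
    bin_centers: np.ndarray
    mean_force: np.ndarray  # kcal/mol/A
    force_variance: np.ndarray  # sigma^2 per bin
    n_samples: np.ndarray  # K per bin
    tau: np.ndarray  # correlation length per bin, in samples
    window_id: str = ""

    def __post_init__(self) -> None:
        for name in ("bin_centers", "mean_force", "force_variance", "n_samples", "tau"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        n = len(self.bin_centers)
        for name in ("mean_force", "force_variance", "n_samples", "tau"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match bin count")

    @classmethod
    def from_csv(cls, path, interval=None, window_id: str = "") -> "WindowForceData":
        df = pd.read_csv(path)
        centers = df["bin_center"].to_numpy()
        if interval is None:
            half = (centers[1] - centers[0]) / 2 if len(centers) > 1 else 0.5
            interval = (centers[0] - half, centers[-1] + half)
        return cls(
            tuple(interval),
            centers,
            df["mean_force"].to_numpy(),
            df["force_variance"].to_numpy(),
            df["n_samples"].to_numpy(),
            df["tau"].to_numpy(),
            window_id=window_id or str(path),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "mean_force": self.mean_force,
                "force_variance": self.force_variance,
                "n_samples": self.n_samples,
                "tau": self.tau,
            }
        ).to_csv(path, index=False, float_format="%.6g")

    def undersampled(self, min_samples: float) -> np.ndarray:
        """Boolean mask of bins whose sampling falls below the minimum rule."""
        return self.n_samples < min_samples


def abf_error(
    window: WindowForceData, interval: tuple[float, float] | None = None
) -> float:
    """SD bound (xi_b - xi_a) sigma / sqrt(K) * sqrt(1 + 2 tau) in kcal/mol.

    K is the (mean) number of force evaluations accumulated per bin over
    the requested interval; sigma^2 the pooled force variance and tau the
    mean force correlation length in samples.  With per-bin K the formula
    is a genuine upper limit on the standard error of the integrated
    free-energy difference: it treats the whole interval as if it carried a
    single bin's worth of statistics, whereas the actual estimator averages
    over all bins in the span.
    """
    xi_a, xi_b = interval if interval is not None else window.interval
    mask = (window.bin_centers >= min(xi_a, xi_b) - 1e-9) & (
        window.bin_centers <= max(xi_a, xi_b) + 1e-9
    )
    if not mask.any():
        mask = np.ones_like(window.bin_centers, dtype=bool)
    K = float(window.n_samples[mask].mean())
    if K <= 0:
        raise ValueError("no force samples in the requested interval")
    sigma = float(np.sqrt(window.force_variance[mask].mean()))
    tau = float(window.tau[mask].mean())
    if tau < 0:
        raise ValueError("correlation length must be non-negative")
    return abs(xi_b - xi_a) * sigma / np.sqrt(K) * np.sqrt(1.0 + 2.0 * tau)


@dataclass
class PMFProfile:
    """Free energy A(xi) on a discrete colvar grid with per-point SD bounds."""

    xi: np.ndarray
    A: np.ndarray
    sd_bound: np.ndarray
    window_id: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"xi": self.xi, "A": self.A, "sd_bound": self.sd_bound,
             "window_id": self.window_id or [""] * len(self.xi)}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


def _window_pmf(w: WindowForceData) -> tuple[np.ndarray, np.ndarray]:
    """Integrate -<F> over one window's bins (trapezoid, A=0 at first bin)."""
    force = w.mean_force.copy()
    empty = w.n_samples <= 0
    if empty.any():
        import warnings

        warnings.warn(
            f"window {w.window_id}: {int(empty.sum())} empty bin(s) interpolated",
            stacklevel=3,
        )
        good = ~empty
        force[empty] = np.interp(w.bin_centers[empty], w.bin_centers[good], force[good])
    A = cumulative_trapezoid(-force, w.bin_centers, initial=0.0)
    return w.bin_centers, A


def integrate_pmf(windows: Sequence[WindowForceData]) -> PMFProfile:
    """Assemble a PMF from overlapping windows of mean-force bins.

    Each window is integrated separately; constant offsets are then found
    by least squares so that windows agree on their overlaps, and the
    global minimum is gauged to zero.  Windows must jointly cover a
    connected interval.
    """
    if not windows:
        raise ValueError("no windows supplied")
    ws = sorted(windows, key=lambda w: w.interval[0])
    for a, b in zip(ws, ws[1:]):
        if b.interval[0] > a.interval[1] + 1e-9:
            raise ValueError(
                f"disconnected coverage: gap between {a.interval} and {b.interval}"
            )
    pieces = [_window_pmf(w) for w in ws]

    def _interp(piece, grid):
        x, A = piece
        if len(x) >= 4:
            from scipy.interpolate import CubicSpline

            return CubicSpline(x, A, bc_type="not-a-knot")(grid)
        return np.interp(grid, x, A)

    n = len(ws)
    offsets = np.zeros(n)
    if n > 1:
        # least-squares offsets c_k minimizing overlap mismatch, c_0 = 0
        rows, rhs = [], []
        for i in range(n):
            for j in range(i + 1, n):
                lo = max(ws[i].interval[0], ws[j].interval[0])
                hi = min(ws[i].interval[1], ws[j].interval[1])
                if hi <= lo + 1e-9:
                    continue
                grid = np.linspace(lo, hi, 11)
                Ai = _interp(pieces[i], grid)
                Aj = _interp(pieces[j], grid)
                for d in Ai - Aj:
                    row = np.zeros(n)
                    row[j], row[i] = 1.0, -1.0
                    rows.append(row)
                    rhs.append(d)
        if rows:
            M = np.array(rows)[:, 1:]  # gauge: c_0 = 0
            sol, *_ = np.linalg.lstsq(M, np.array(rhs), rcond=None)
            offsets[1:] = sol
    xi_all, A_all, wid_all = [], [], []
    for w, (x, A), c in zip(ws, pieces, offsets):
        xi_all.append(x)
        A_all.append(A + c)
        wid_all.extend([w.window_id] * len(x))
    xi = np.concatenate(xi_all)
    A = np.concatenate(A_all)
    # merge duplicate grid points (overlaps) by averaging
    order = np.argsort(xi)
    xi, A = xi[order], A[order]
    wid = [wid_all[k] for k in order]
    merged_xi, merged_A, merged_w = [], [], []
    i = 0
    while i < len(xi):
        j = i
        while j + 1 < len(xi) and xi[j + 1] - xi[i] < 1e-6:
            j += 1
        merged_xi.append(xi[i])
        merged_A.append(A[i : j + 1].mean())
        merged_w.append(wid[i])
        i = j + 1
    xi = np.array(merged_xi)
    A = np.array(merged_A)
    A -= A.min()
    sd = np.empty_like(A)
    for k, x in enumerate(xi):
        # bound for the span from the global minimum to this point, taken
        # from the window that owns the point
        w = next(w for w in ws if w.interval[0] - 1e-9 <= x <= w.interval[1] + 1e-9)
        sd[k] = abf_error(w, (xi[np.argmin(A)], x)) if len(xi) > 1 else 0.0
    return PMFProfile(xi, A, sd, merged_w)


# ---------------------------------------------------------------------------
# blocking analysis (Flyvbjerg & Petersen)


@dataclass
class BlockingResult:
    """Standard-error estimates per blocking level and the derived tau_c."""

    levels: pd.DataFrame  # columns: level, block_size, n_blocks, se, se_err
    se_naive: float
    se_plateau: float
    tau_c: float  # in time units (dt * samples)
    plateau_found: bool


def blocking_analysis(series: np.ndarray, dt: float = 1.0) -> BlockingResult:
    """Flyvbjerg-Petersen pairwise block averaging of a correlated series.

    Successively halves the series by averaging neighbour pairs; the SE of
    the mean per level climbs to a plateau once blocks exceed the
    correlation length.  The integrated correlation time follows from
    tau_c = dt ((SE_plateau / SE_naive)^2 - 1) / 2.  If no plateau is
    reached before fewer than 16 blocks remain, the last level is returned
    as a lower bound with ``plateau_found`` false.
    """
    x = np.asarray(series, float)
    n = x.size
    if n < 64:
        raise ValueError(f"series too short for blocking analysis ({n} < 64)")
    rows = []
    level = 0
    cur = x.copy()
    while cur.size >= 16:
        m = cur.size
        var = cur.var(ddof=1)
        se = np.sqrt(var / m)
        se_err = se / np.sqrt(2.0 * (m - 1))
        rows.append((level, 2**level, m, se, se_err))
        cur = (cur[: m - m % 2 : 2] + cur[1 : m - m % 2 + 1 : 2]) / 2.0
        level += 1
    df = pd.DataFrame(rows, columns=["level", "block_size", "n_blocks", "se", "se_err"])
    se_naive = float(df["se"].iloc[0])
    # plateau: first level from which successive SE increments stay within
    # their error bars for a few consecutive levels.  Levels with fewer
    # than 32 blocks have >10% relative noise on the SE itself and are
    # excluded from both detection and averaging.
    plateau_found = False
    se = df["se"].to_numpy()
    se_err = df["se_err"].to_numpy()
    eligible = int((df["n_blocks"] >= 32).sum())
    se_plateau = float(se[eligible - 1])
    for k in range(eligible - 1):
        stop = min(k + 3, eligible - 1)
        if all(abs(se[j + 1] - se[j]) <= se_err[j + 1] for j in range(k, stop)):
            se_plateau = float(se[k : min(k + 4, eligible)].mean())
            plateau_found = True
            break
    if not plateau_found:
        import warnings

        warnings.warn(
            "no blocking plateau before blocks < 16; tau_c is a lower bound",
            stacklevel=2,
        )
    ratio2 = (se_plateau / se_naive) ** 2
    tau_c = dt * (ratio2 - 1.0) / 2.0
    return BlockingResult(df, se_naive, se_plateau, max(tau_c, 0.0), plateau_found)


def minimum_sampling_flags(
    windows: Sequence[WindowForceData], *, min_time: float = 5000.0, dt: float = 10.0
) -> pd.DataFrame:
    """Flag force bins sampled for less than the minimum-time rule.

    ``min_time`` and ``dt`` are in ps (defaults: 5 ns minimum at 10 ps per
    sample, the decorrelation-based rule for junction arm roll).
    """
    rows = []
    for w in windows:
        mask = w.undersampled(min_time / dt)
        for c, k, flag in zip(w.bin_centers, w.n_samples, mask):
            rows.append(
                {"window_id": w.window_id, "bin_center": c,
                 "n_samples": k, "sampled_time": k * dt, "undersampled": bool(flag)}
            )
    return pd.DataFrame(rows)
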