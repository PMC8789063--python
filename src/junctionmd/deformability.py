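"""Per-step covariance, harmonic stiffness and configurational volume.

Within a harmonic (Gaussian) model of base-pair step fluctuations the 6x6
covariance of the step parameters C_h and the stiffness matrix F_h are
related by C_h = k_B T F_h^{-1}.  The determinant of C_h (the product of
its eigenvalues) is the configurational volume, a scalar deformability
summary in A^3 deg^3 that folds in the off-diagonal couplings.  Deviation
reports compare per-step means, stiffness diagonals and volumes against a
B-form duplex reference matched by dinucleotide context, suppressing
deviations below display thresholds (0.2 A / 2 deg by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, KB_KCAL
from .geometry import PARAM_NAMES, StepParams, StepSeries
from .schema import StepLabel


@dataclass
class StepCovariance:
    """Sample mean and 6x6 covariance of one step's parameters."""

    label: StepLabel
    C_h: np.ndarray
    n_frames: int
    mean: StepParams
    sequence: str = ""

    def __post_init__(self) -> None:
        C = np.asarray(self.C_h, float)
        if C.shape != (6, 6):
            raise ValueError("C_h must be 6x6")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("C_h must be symmetric")
        w = np.linalg.eigvalsh(C)
        if w.min() < -1e-8 * max(np.trace(C), 1.0):
            raise ValueError("C_h has a negative eigenvalue beyond tolerance")
        self.C_h = C


@dataclass
class StiffnessMatrix:
    """Harmonic stiffness F_h = k_B T C_h^-1 (kcal/mol per A^2, A deg, deg^2)."""

    label: StepLabel
    F_h: np.ndarray
    temperature: float
    condition_number: float = np.nan
    sequence: str = ""

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.F_h)


def step_covariance(series: StepSeries) -> StepCovariance:
    """Sample mean and covariance (n-1 denominator) of a step series."""
    n = series.n_frames
    if n < 7:
        raise ValueError(
            f"{series.label.render()}: {n} frames < 7; covariance singular"
        )
    mean = series.values.mean(axis=0)
    C = np.cov(series.values, rowvar=False, ddof=1)
    return StepCovariance(
        label=series.label,
        C_h=C,
        n_frames=n,
        mean=StepParams.from_array(mean),
        sequence=series.sequence,
    )


def stiffness_from_covariance(
    cov: StepCovariance, temperature: float = DEFAULT_TEMPERATURE
) -> StiffnessMatrix:
    """Invert the covariance: F_h = k_B T C_h^-1."""
    C = cov.C_h
    condition = float(np.linalg.cond(C))
    w = np.linalg.eigvalsh(C)
    if w.min() <= 0 or condition > 1e12:
        raise np.linalg.LinAlgError(
            f"{cov.label.render()}: C_h is singular (cond={condition:.3g}); "
            "thin the series or pass a pseudo-inverse explicitly"
        )
    F = KB_KCAL * temperature * np.linalg.inv(C)
    F = (F + F.T) / 2.0
    return StiffnessMatrix(
        label=cov.label,
        F_h=F,
        temperature=temperature,
        condition_number=condition,
        sequence=cov.sequence,
    )


def configurational_volume(cov: StepCovariance) -> float:
    """det(C_h): the configurational volume in A^3 deg^3."""
    det = float(np.linalg.det(cov.C_h))
    if det <= 0:
        raise ValueError(
            f"{cov.label.render()}: non-positive det(C_h); data degenerate"
        )
    return det


# ---------------------------------------------------------------------------
# deviation reports (hexplot content of the mean/stiffness/volume figures)

#: suppression thresholds: translations (A), rotations (deg)
MEAN_THRESHOLDS = (0.2, 2.0)
#: display ring scales for mean deviations: (inner, outer) per unit class
MEAN_RINGS = {"translation": (0.5, 1.0), "rotation": (5.0, 10.0)}
#: ring scales for stiffness-diagonal deviations (kcal/mol/A^2, kcal/mol/deg^2)
STIFFNESS_RINGS = {"translation": (1.0, 2.0), "rotation": (0.005, 0.01)}
#: log10 ring scales for configurational volumes (A^3 deg^3)
VOLUME_RINGS = (10.0, 100.0)

_TRANSLATIONS = PARAM_NAMES[:3]


@dataclass
class DeviationReport:
    """Signed per-step deviations from a B-form reference, display-ready."""

    table: pd.DataFrame
    mean_thresholds: tuple[float, float] = MEAN_THRESHOLDS
    mean_rings: dict = field(default_factory=lambda: dict(MEAN_RINGS))
    stiffness_rings: dict = field(default_factory=lambda: dict(STIFFNESS_RINGS))
    volume_rings: tuple[float, float] = VOLUME_RINGS

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.4f")


@dataclass
class ReferenceTable:
    """B-form reference means/stiffness by dinucleotide context.

    Backed by a DataFrame with columns ``dinucleotide``, the six parameter
    means, the six stiffness diagonal entries (prefixed ``k_``), an optional
    ``volume`` and a ``source`` tag (e.g. own simulation vs literature).
    """

    frame: pd.DataFrame

    @classmethod
    def read_csv(cls, path) -> "ReferenceTable":
        return cls(pd.read_csv(path))

    def lookup(self, dinucleotide: str) -> pd.Series:
        hit = self.frame[self.frame["dinucleotide"] == dinucleotide]
        if hit.empty:
            raise KeyError(dinucleotide)
        return hit.iloc[0]


def reference_from_steps(
    covs: Sequence[StepCovariance],
    stiffs: Sequence[StiffnessMatrix],
    source: str = "simulation",
) -> ReferenceTable:
    """Build a reference table from analyzed duplex steps, keyed by context."""
    rows = {}
    for cov, st in zip(covs, stiffs):
        row = {"dinucleotide": cov.sequence, "source": source}
        for i, nm in enumerate(PARAM_NAMES):
            row[nm] = cov.mean.as_array()[i]
            row[f"k_{nm}"] = st.diagonal[i]
        row["volume"] = configurational_volume(cov)
        rows.setdefault(cov.sequence, []).append(row)
    # average duplicated contexts
    merged = []
    for seq, group in rows.items():
        df = pd.DataFrame(group)
        agg = df.drop(columns=["dinucleotide", "source"]).mean()
        merged.append({"dinucleotide": seq, "source": source, **agg.to_dict()})
    return ReferenceTable(pd.DataFrame(merged))


def deviation_report(
    covs: Sequence[StepCovariance],
    stiffs: Sequence[StiffnessMatrix],
    reference: ReferenceTable,
    *,
    fallback: ReferenceTable | None = None,
    mean_thresholds: tuple[float, float] = MEAN_THRESHOLDS,
) -> DeviationReport:
    """Signed deviations of means, stiffness diagonals and volumes vs B-form.

    Steps are matched to the reference by dinucleotide context; contexts
    absent from the primary reference fall back to a user-supplied
    literature table when given (source recorded per step).  Mean
    deviations smaller than the thresholds are flagged suppressed.
    """
    thr_t, thr_r = mean_thresholds
    records = []
    for cov, st in zip(covs, stiffs):
        seq = cov.sequence
        try:
            ref = reference.lookup(seq)
        except KeyError:
            if fallback is None:
                raise KeyError(
                    f"step {cov.label.render()}: no reference for context {seq!r}"
                )
            ref = fallback.lookup(seq)
        vol = configurational_volume(cov)
        for i, nm in enumerate(PARAM_NAMES):
            thr = thr_t if nm in _TRANSLATIONS else thr_r
            dmean = cov.mean.as_array()[i] - ref[nm]
            records.append(
                {
                    "label": cov.label.render(),
                    "sequence": seq,
                    "quantity": f"mean_{nm}",
                    "value": cov.mean.as_array()[i],
                    "deviation": dmean,
                    "suppressed": bool(abs(dmean) < thr),
                    "reference_source": ref["source"],
                }
            )
            records.append(
                {
                    "label": cov.label.render(),
                    "sequence": seq,
                    "quantity": f"stiffness_{nm}",
                    "value": st.diagonal[i],
                    "deviation": st.diagonal[i] - ref[f"k_{nm}"],
                    "suppressed": False,
                    "reference_source": ref["source"],
                }
            )
        records.append(
            {
                "label": cov.label.render(),
                "sequence": seq,
                "quantity": "volume",
                "value": vol,
                "deviation": vol - ref.get("volume", np.nan),
                "suppressed": False,
                "reference_source": ref["source"],
            }
        )
    return DeviationReport(pd.DataFrame(records), mean_thresholds=mean_thresholds)
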