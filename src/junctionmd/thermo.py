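"""Configurational entropy, end-state free-energy bookkeeping, isomer ratios.

Three pieces of thermodynamic accounting for junction isomerization:

* Schlitter's quasiharmonic entropy: an upper bound on the configurational
  entropy from the mass-weighted coordinate covariance,
  ``S' = (k/2) sum ln[1 + (kT e^2/hbar^2) <q_i^2>]``, where <q_i^2> are the
  eigenvalues of M^(1/2) C M^(1/2).
* MM-PBSA end-state combination over externally computed per-frame (and
  optionally per-base) term tables: G_solvated = E_gas + dG_solvation - T S,
  with E_gas = E_int + E_ele + E_vdW and dG_solvation = dG_PB + dG_SA.  The
  PB/SA solvers themselves are external; this module only combines their
  outputs.
* The Boltzmann relation between stacked-conformer populations and the
  isomerization free energy, ddG = -RT ln(fr_IsoI / fr_IsoII).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import (
    AMU_SI,
    ANGSTROM_SI,
    AVOGADRO,
    DEFAULT_TEMPERATURE,
    HBAR_SI,
    J_PER_KCAL,
    KB_KCAL,
    KB_SI,
    R_KJ,
)

GAS_TERMS = ("INT", "ELE", "VDW")
SOLV_TERMS = ("PB", "SA")
ALL_TERMS = GAS_TERMS + SOLV_TERMS


# ---------------------------------------------------------------------------
# Schlitter entropy


@dataclass
class EntropyEstimate:
    """Quasiharmonic entropy upper bound S' with its convergence series."""

    S_prime: float  # kcal mol^-1 K^-1
    temperature: float
    convergence: pd.DataFrame | None = None  # columns: n_frames, S_prime
    converged: bool = True

    def minus_TS(self) -> float:
        """-T S' in kcal/mol."""
        return -self.temperature * self.S_prime


def _schlitter_from_covariance(
    C: np.ndarray, masses: np.ndarray, temperature: float
) -> float:
    """S' in kcal mol^-1 K^-1 from a coordinate covariance (A^2) and amu masses."""
    C = np.asarray(C, float)
    n = C.shape[0]
    m = np.repeat(np.asarray(masses, float), 3) if 3 * len(masses) == n else np.asarray(masses, float)
    if m.shape[0] != n:
        raise ValueError("mass vector does not match covariance dimension")
    if (m <= 0).any():
        raise ValueError("masses must be positive")
    sqrt_m = np.sqrt(m)
    Cp = C * np.outer(sqrt_m, sqrt_m)  # M^{1/2} C M^{1/2}
    q2 = np.linalg.eigvalsh((Cp + Cp.T) / 2.0)
    tol = -1e-8 * max(np.trace(Cp), 1.0)
    if q2.min() < tol:
        raise ValueError("covariance has a negative eigenvalue beyond tolerance")
    q2 = np.clip(q2, 0.0, None)
    # (k T e^2 / hbar^2) * m <q^2>, everything in SI; q2 carries amu A^2
    alpha = (
        KB_SI * temperature * np.e**2 / HBAR_SI**2 * AMU_SI * ANGSTROM_SI**2
    )
    s_per_molecule = 0.5 * KB_SI * np.log1p(alpha * q2).sum()  # J/K
    return float(s_per_molecule * AVOGADRO / J_PER_KCAL)


def schlitter_entropy(
    covariance: np.ndarray,
    masses: Sequence[float],
    temperature: float = DEFAULT_TEMPERATURE,
    *,
    frames: np.ndarray | None = None,
    n_checkpoints: int = 10,
    convergence_rtol: float = 0.01,
) -> EntropyEstimate:
    """Schlitter upper-bound entropy from a mass-weighted covariance.

    When the raw ``frames`` (n_frames, n_atoms, 3) are provided, S' is also
    evaluated on growing frame prefixes; convergence is declared when the
    relative change over the last 20% of frames is below
    ``convergence_rtol``.
    """
    S = _schlitter_from_covariance(covariance, np.asarray(masses, float), temperature)
    conv = None
    converged = True
    if frames is not None:
        frames = np.asarray(frames, float)
        n = frames.shape[0]
        X = frames.reshape(n, -1)
        ns = np.unique(np.linspace(max(8, n // n_checkpoints), n, n_checkpoints).astype(int))
        rows = []
        for k in ns:
            Ck = np.cov(X[:k], rowvar=False, ddof=0)
            rows.append((k, _schlitter_from_covariance(Ck, np.asarray(masses, float), temperature)))
        conv = pd.DataFrame(rows, columns=["n_frames", "S_prime"])
        tail = conv[conv["n_frames"] >= 0.8 * n]["S_prime"].to_numpy()
        if len(tail) >= 2 and tail[-1] > 0:
            converged = bool(abs(tail[-1] - tail[0]) / tail[-1] < convergence_rtol)
    return EntropyEstimate(S, temperature, conv, converged)


def gaussian_entropy_exact(
    covariance: np.ndarray, masses: Sequence[float], temperature: float
) -> float:
    """Quantum-harmonic-oscillator entropy of the same Gaussian model.

    Reference value bounded above by the Schlitter estimate; useful as an
    oracle in tests.  Returns kcal mol^-1 K^-1.
    """
    C = np.asarray(covariance, float)
    m = np.repeat(np.asarray(masses, float), 3) if 3 * len(masses) == C.shape[0] else np.asarray(masses, float)
    sqrt_m = np.sqrt(m)
    Cp = C * np.outer(sqrt_m, sqrt_m)
    q2 = np.clip(np.linalg.eigvalsh((Cp + Cp.T) / 2.0), 0.0, None)
    kT = KB_SI * temperature
    q2_si = q2 * AMU_SI * ANGSTROM_SI**2
    # hbar omega / kT for classical variance <q^2> = kT/omega^2 (mass-weighted)
    with np.errstate(divide="ignore"):
        x = HBAR_SI / np.sqrt(kT * q2_si)
    s = 0.0
    for xi in x[np.isfinite(x) & (x > 0)]:
        s += KB_SI * (xi / np.expm1(xi) - np.log1p(-np.exp(-xi)))
    return float(s * AVOGADRO / J_PER_KCAL)


# ---------------------------------------------------------------------------
# MM-PBSA combination


@dataclass
class MMPBSAResult:
    """Frame-averaged end-state totals, optionally with per-base profiles."""

    totals: pd.Series  # E_gas, dG_solvation, dG_solvated, per-term means
    per_base: pd.DataFrame | None = None  # index (strand/base), term columns
    entropy_term: float | None = None  # -T S' (kcal/mol) when converged
    entropy_flag: str = "omitted"


def read_energy_table(path) -> pd.DataFrame:
    """Read a tab-separated term table: FRAME [BASE [STRAND]] INT ELE VDW PB SA."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("FRAME", *ALL_TERMS) if c not in df.columns]
    if missing:
        raise ValueError(f"energy table lacks columns: {', '.join(missing)}")
    return df


def _check_complete(terms: pd.DataFrame) -> None:
    if terms[list(ALL_TERMS)].isna().any().any():
        bad = terms[terms[list(ALL_TERMS)].isna().any(axis=1)]["FRAME"].unique()
        raise ValueError(f"incomplete term rows for frames {bad[:5]}")


def mmpbsa_combine(
    terms: pd.DataFrame,
    entropy: EntropyEstimate | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
) -> MMPBSAResult:
    """Combine per-frame MM-PBSA terms into end-state totals.

    ``terms`` carries one row per frame (molecular) or per frame and base
    (decomposed); both may be present, in which case per-base sums are
    validated against the molecular rows.  The solute-entropy term is
    included only when the estimate is flagged converged, mirroring how
    unconverged quasiharmonic entropies are reported alongside, not inside,
    the totals.
    """
    _check_complete(terms)
    has_base = "BASE" in terms.columns and terms["BASE"].notna().any()
    mol = terms[terms["BASE"].isna()] if has_base else terms
    per_base = None
    if has_base:
        base_rows = terms[terms["BASE"].notna()]
        keys = ["STRAND", "BASE"] if "STRAND" in terms.columns else ["BASE"]
        per_base = base_rows.groupby(keys)[list(ALL_TERMS)].mean()
        per_base["E_gas"] = per_base[list(GAS_TERMS)].sum(axis=1)
        per_base["dG_solvation"] = per_base[list(SOLV_TERMS)].sum(axis=1)
        per_base["TOTAL"] = per_base["E_gas"] + per_base["dG_solvation"]
        if mol.empty:
            mol = base_rows.groupby("FRAME")[list(ALL_TERMS)].sum().reset_index()
        else:
            frame_sums = base_rows.groupby("FRAME")[list(ALL_TERMS)].sum()
            frame_mol = mol.set_index("FRAME")[list(ALL_TERMS)]
            common = frame_sums.index.intersection(frame_mol.index)
            if len(common) and not np.allclose(
                frame_sums.loc[common], frame_mol.loc[common], atol=1e-3
            ):
                raise ValueError(
                    "per-base terms do not sum to the molecular terms (>1e-3)"
                )
    means = mol[list(ALL_TERMS)].mean()
    e_gas = float(means[list(GAS_TERMS)].sum())
    dg_solv = float(means[list(SOLV_TERMS)].sum())
    totals = pd.Series(
        {**means.to_dict(), "E_gas": e_gas, "dG_solvation": dg_solv,
         "dG_solvated": e_gas + dg_solv}
    )
    ts = None
    flag = "omitted"
    if entropy is not None:
        if entropy.converged:
            ts = entropy.minus_TS()
            totals["dG_solvated"] += ts
            totals["-TS"] = ts
            flag = "included"
        else:
            flag = "omitted_unconverged"
    return MMPBSAResult(totals, per_base, ts, flag)


def isomer_difference(iso1: MMPBSAResult, iso2: MMPBSAResult) -> pd.DataFrame:
    """Per-base ddE = dE_Iso1 - dE_Iso2 profiles (requires decomposed tables)."""
    if iso1.per_base is None or iso2.per_base is None:
        raise ValueError("both isomers need per-base decompositions")
    a, b = iso1.per_base, iso2.per_base
    if not a.index.equals(b.index):
        only_a = a.index.difference(b.index).tolist()
        only_b = b.index.difference(a.index).tolist()
        raise ValueError(
            f"mismatched base sets between isomers: {only_a[:4]} vs {only_b[:4]}"
        )
    return a - b


# ---------------------------------------------------------------------------
# conformer-ratio thermodynamics


@dataclass
class IsomerThermo:
    """Populations of the two stacked conformers and their free-energy gap."""

    fr_IsoI: float
    fr_IsoII: float
    temperature: float
    ddG_kcal: float
    ddG_kJ: float
    at_bound: bool = False

    @property
    def ratio(self) -> float:
        return self.fr_IsoI / self.fr_IsoII if self.fr_IsoII > 0 else np.inf


def isomer_dg(
    fr_IsoI: float, temperature: float = DEFAULT_TEMPERATURE
) -> IsomerThermo:
    """ddG = -RT ln(fr_IsoI / fr_IsoII), with fr_IsoII = 1 - fr_IsoI.

    Fractions at exactly 0 or 1 return signed infinity with ``at_bound``
    set, matching how bounded populations (e.g. >= 0.95) propagate to
    free-energy bounds.
    """
    if not 0.0 <= fr_IsoI <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fr_IsoI}")
    fr2 = 1.0 - fr_IsoI
    if fr_IsoI in (0.0, 1.0):
        sign = -1.0 if fr_IsoI == 1.0 else 1.0
        return IsomerThermo(fr_IsoI, fr2, temperature,
                            sign * np.inf, sign * np.inf, at_bound=True)
    lnr = np.log(fr_IsoI / fr2)
    return IsomerThermo(
        fr_IsoI,
        fr2,
        temperature,
        ddG_kcal=-KB_KCAL * temperature * lnr,
        ddG_kJ=-R_KJ * temperature * lnr,
    )
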