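"""Readers/writers for ensembles, step tables, mode sets and run configs.

Coordinate ensembles come in as multi-model PDB files (MODEL/ENDMDL) or as
a directory of per-frame PDBs; strand labels (Roman numerals I-IV) map to
PDB chain identifiers through an optional JSON chain map.  Step-parameter
tables are written in a 3DNA-style dialect (one header line, then label +
six parameters, tab-separated, 4 decimals) and in long-format CSV with a
time column.  Residue numbering is 1-based user-facing.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .geometry import PARAM_NAMES, StepSeries
from .schema import parse_step_label

logger = logging.getLogger("junctionmd")


@dataclass
class StructureEnsemble:
    """Ordered coordinate frames with stable (strand, residue, atom) indexing."""

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    chain_ids: np.ndarray  # per atom
    res_ids: np.ndarray  # per atom, 1-based
    atom_names: np.ndarray  # per atom
    res_names: np.ndarray | None = None
    chain_map: Mapping[str, str] | None = None  # strand id -> chain id
    _index: dict = field(default_factory=dict, repr=False)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def _chain_for(self, strand: str) -> str:
        if self.chain_map and strand in self.chain_map:
            return self.chain_map[strand]
        return strand

    def base_atoms(self, frame: int, strand: str, position: int) -> dict[str, np.ndarray]:
        key = (self._chain_for(strand), position)
        if key not in self._index:
            mask = (self.chain_ids == key[0]) & (self.res_ids == key[1])
            idx = np.where(mask)[0]
            if idx.size == 0:
                raise KeyError(
                    f"no atoms for strand {strand!r} (chain {key[0]!r}) "
                    f"residue {position}"
                )
            self._index[key] = [(k, self.atom_names[k]) for k in idx]
        return {name: self.coords[frame, k] for k, name in self._index[key]}

    def backbone_coordinates(
        self, atom_names: Sequence[str] = ("P", "O5'", "C5'", "C4'", "C3'", "O3'")
    ) -> np.ndarray:
        mask = np.isin(self.atom_names, list(atom_names))
        return self.coords[:, mask, :]


def _stack_to_ensemble(stack, chain_map=None) -> StructureEnsemble:
    coords = stack.coord
    if coords.ndim == 2:
        coords = coords[None]
    return StructureEnsemble(
        coords=np.asarray(coords, float),
        chain_ids=np.asarray(stack.chain_id),
        res_ids=np.asarray(stack.res_id, int),
        atom_names=np.asarray(stack.atom_name),
        res_names=np.asarray(stack.res_name),
        chain_map=chain_map,
    )


def read_structure_ensemble(
    path, chain_map: Mapping[str, str] | str | Path | None = None
) -> StructureEnsemble:
    """Read a multi-model PDB file or a directory of per-frame PDBs.

    Altloc 'A' is preferred; non-PDB files inside a frame directory are
    skipped with a log entry; inconsistent atom counts across frames raise
    an error naming the offending frames.
    """
    if isinstance(chain_map, (str, Path)):
        with open(chain_map) as fh:
            chain_map = json.load(fh)
    path = Path(path)
    if path.is_dir():
        frames = []
        names = []
        for p in sorted(path.iterdir()):
            if p.suffix.lower() != ".pdb":
                logger.info("skipping non-PDB file %s", p.name)
                continue
            pdb = PDBFile.read(str(p))
            frames.append(pdb.get_structure(model=1, altloc="first"))
            names.append(p.name)
        if not frames:
            raise FileNotFoundError(f"no PDB files in directory {path}")
        counts = {n: f.array_length() for n, f in zip(names, frames)}
        if len(set(counts.values())) > 1:
            raise ValueError(f"inconsistent atom counts across frames: {counts}")
        stack = struc.stack(frames)
        return _stack_to_ensemble(stack, chain_map)
    pdb = PDBFile.read(str(path))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stack = pdb.get_structure(altloc="first")
    return _stack_to_ensemble(stack, chain_map)


def write_structure_ensemble(ensemble, path) -> None:
    """Write an ensemble (io or synth flavour) as a multi-model PDB."""
    n_frames = ensemble.n_frames
    if hasattr(ensemble, "atoms"):  # SyntheticEnsemble
        atoms = ensemble.atoms
        n_atoms = len(atoms)
        arr = struc.AtomArray(n_atoms)
        arr.chain_id = np.array([_chain_letter(s) for s, _, _ in atoms])
        arr.res_id = np.array([p for _, p, _ in atoms], int)
        arr.atom_name = np.array([n for _, _, n in atoms])
        res_names = []
        for s, p, _ in atoms:
            base = ensemble.sequence_by_strand[s][p - 1]
            res_names.append("D" + base)
        arr.res_name = np.array(res_names)
        arr.element = np.array([n[0] for _, _, n in atoms])
        coords = ensemble.coords
    else:
        n_atoms = ensemble.n_atoms
        arr = struc.AtomArray(n_atoms)
        arr.chain_id = ensemble.chain_ids
        arr.res_id = ensemble.res_ids
        arr.atom_name = ensemble.atom_names
        arr.res_name = (
            ensemble.res_names
            if ensemble.res_names is not None
            else np.full(n_atoms, "DN")
        )
        arr.element = np.array([n[0] for n in ensemble.atom_names])
        coords = ensemble.coords
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    for cat in arr.get_annotation_categories():
        stack.set_annotation(cat, arr.get_annotation(cat))
    stack.coord = np.asarray(coords, np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


_CHAIN_LETTERS = {"I": "A", "II": "B", "III": "C", "IV": "D", "R": "R", "S": "S"}


def _chain_letter(strand: str) -> str:
    return _CHAIN_LETTERS.get(strand, strand[:1])


def default_chain_map(strands: Sequence[str]) -> dict[str, str]:
    """Strand-id -> chain-id map matching :func:`write_structure_ensemble`."""
    return {s: _chain_letter(s) for s in strands}


# ---------------------------------------------------------------------------
# step tables


def write_step_table(series: Mapping[str, StepSeries], path) -> None:
    """3DNA-dialect per-step table of mean parameters (tab-separated)."""
    lines = ["label\t" + "\t".join(PARAM_NAMES)]
    for key in series:
        s = series[key]
        mean = s.values.mean(axis=0)
        lines.append(key + "\t" + "\t".join(f"{v:.4f}" for v in mean))
    Path(path).write_text("\n".join(lines) + "\n")


def write_step_series_csv(series: Mapping[str, StepSeries], path) -> None:
    """Long-format CSV of full time series with a time column (ps)."""
    frames = []
    for key in series:
        s = series[key]
        df = pd.DataFrame(s.values, columns=list(PARAM_NAMES))
        df.insert(0, "time", s.times)
        df.insert(0, "label", key)
        df["sequence"] = s.sequence
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.4f")


def read_step_series_csv(path) -> dict[str, StepSeries]:
    df = pd.read_csv(path)
    out = {}
    for key, grp in df.groupby("label", sort=False):
        times = grp["time"].to_numpy()
        dt = float(times[1] - times[0]) if len(times) > 1 else 10.0
        seq = str(grp["sequence"].iloc[0]) if "sequence" in grp else ""
        out[key] = StepSeries(
            parse_step_label(key),
            grp[list(PARAM_NAMES)].to_numpy(),
            dt,
            sequence=seq,
        )
    return out


# ---------------------------------------------------------------------------
# mode sets


def write_mode_set(modeset, path_prefix) -> None:
    """JSON header + columnar eigenvector text + mean-structure PDB."""
    prefix = Path(path_prefix)
    header = {
        "n_modes": int(len(modeset.eigenvalues)),
        "n_atoms": int(modeset.mean.shape[0]),
        "n_discarded_zero_modes": int(modeset.n_discarded_zero_modes),
        "rigid_mass": float(modeset.rigid_mass),
        "eigenvalues_A2": [float(v) for v in modeset.eigenvalues],
    }
    prefix.with_suffix(".json").write_text(json.dumps(header, indent=2) + "\n")
    np.savetxt(prefix.with_suffix(".vecs.txt"), modeset.eigenvectors.T, fmt="%.8e")
    np.savetxt(prefix.with_suffix(".mean.txt"), modeset.mean, fmt="%.4f")


def read_mode_set(path_prefix):
    from .essential import ModeSet

    prefix = Path(path_prefix)
    header = json.loads(prefix.with_suffix(".json").read_text())
    vecs = np.loadtxt(prefix.with_suffix(".vecs.txt"))
    if vecs.ndim == 1:
        vecs = vecs[:, None]
    mean = np.loadtxt(prefix.with_suffix(".mean.txt"))
    return ModeSet(
        eigenvalues=np.array(header["eigenvalues_A2"]),
        eigenvectors=vecs.T,
        mean=mean,
        n_discarded_zero_modes=header["n_discarded_zero_modes"],
        rigid_mass=header["rigid_mass"],
    )


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Resolved run settings; a copy is written next to every output set."""

    temperature: float = 298.0
    seed: int = 0
    output_dir: str = "."
    inputs: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)

    def write(self, path=None) -> Path:
        from . import __version__

        target = Path(path) if path else Path(self.output_dir) / "run_config.json"
        doc = {
            "tool": "junctionmd",
            "version": __version__,
            "temperature": self.temperature,
            "seed": self.seed,
            "inputs": self.inputs,
            "options": self.options,
        }
        target.parent.mkdir(parents=True, exist_ok=True)
        target.write_text(json.dumps(doc, indent=2) + "\n")
        return target
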