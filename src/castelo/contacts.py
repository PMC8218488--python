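"""Trajectory loading and binary ligand-protein contact matrices.

Each trajectory frame is featurized as a binary N×M contact matrix over the
N ligand atoms and M protein atoms: entry (i, j) is 1 iff the two atoms are
within a distance cutoff (closed comparison; default 4.5 Å, hydrogens
included). Contact matrices can then be aggregated over the ligand atoms of
one atom subtype by logical OR, giving the 1×M row fed to the per-subtype
autoencoders.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import ConsistencyError, FormatError, LookupError_, SelectionError

__all__ = [
    "Trajectory",
    "ContactSeries",
    "load_trajectory",
    "compute_contact_series",
    "aggregate_by_subtype",
    "save_contact_series",
    "load_contact_series",
]

DEFAULT_CONTACT_CUTOFF = 4.5  # Å, any-atom pair, hydrogens included
DEFAULT_FRAME_INTERVAL_PS = 20.0


@dataclass
class Trajectory:
    """In-memory coordinates plus ligand/protein atom index lists.

    ``coords`` has shape (T, n_atoms, 3) in Å, frames in simulation-time
    order; ``ligand_indices``/``protein_indices`` index into the atom axis in
    file order and must be disjoint and non-empty.
    """

    coords: np.ndarray
    ligand_indices: np.ndarray
    protein_indices: np.ndarray
    atom_names: list[str]
    atom_types: list[str]
    frame_interval_ps: float = DEFAULT_FRAME_INTERVAL_PS

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.ligand_indices = np.asarray(self.ligand_indices, dtype=int)
        self.protein_indices = np.asarray(self.protein_indices, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ConsistencyError("coords must have shape (T, n_atoms, 3)")
        if self.ligand_indices.size == 0 or self.protein_indices.size == 0:
            raise SelectionError("ligand and protein selections must be non-empty")
        if np.intersect1d(self.ligand_indices, self.protein_indices).size:
            raise ConsistencyError("ligand and protein selections overlap")
        if self.frame_interval_ps <= 0:
            raise ValueError("frame_interval_ps must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_ligand(self) -> int:
        return self.ligand_indices.size

    @property
    def n_protein(self) -> int:
        return self.protein_indices.size

    def ligand_coords(self, frame: int) -> np.ndarray:
        return self.coords[frame, self.ligand_indices]

    def protein_coords(self, frame: int) -> np.ndarray:
        return self.coords[frame, self.protein_indices]


@dataclass
class ContactSeries:
    """Binary contact matrices over time: values has shape (T, N, M)."""

    values: np.ndarray
    cutoff: float
    ligand_labels: list[str] = field(default_factory=list)
    protein_labels: list[str] = field(default_factory=list)
    frame_interval_ps: float = DEFAULT_FRAME_INTERVAL_PS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ConsistencyError("contact values must have shape (T, N, M)")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("contact values must be binary")
        self.values = self.values.astype(np.uint8)
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def load_trajectory(
    topology_path,
    coords_path=None,
    ligand_selection: str = "resname LIG",
    protein_selection: str = "protein",
    frame_interval_ps: float = DEFAULT_FRAME_INTERVAL_PS,
) -> Trajectory:
    """Load a topology (PDB/PSF) + coordinate (DCD/XTC/PDB) pair.

    Selections use the MDAnalysis selection language and must be non-empty
    and disjoint. Atom ordering follows file order. ``coords_path`` may be
    omitted when the topology itself carries frames (multi-model PDB).
    """
    import MDAnalysis as mda

    try:
        if coords_path is None:
            u = mda.Universe(str(topology_path))
        else:
            u = mda.Universe(str(topology_path), str(coords_path))
    except (OSError, ValueError, IndexError, TypeError) as exc:
        raise FormatError(f"could not read trajectory: {exc}") from exc
    if u.atoms.n_atoms == 0:
        raise FormatError(f"no atoms parsed from {topology_path}")

    lig = u.select_atoms(ligand_selection)
    prot = u.select_atoms(protein_selection)
    if lig.n_atoms == 0:
        raise SelectionError(f"ligand selection {ligand_selection!r} matched no atoms")
    if prot.n_atoms == 0:
        raise SelectionError(f"protein selection {protein_selection!r} matched no atoms")
    if np.intersect1d(lig.indices, prot.indices).size:
        raise ConsistencyError("ligand and protein selections overlap")

    coords = np.empty((len(u.trajectory), u.atoms.n_atoms, 3))
    for t, _ in enumerate(u.trajectory):
        coords[t] = u.atoms.positions
    # PSF atoms carry force-field types; PDB falls back to element/name
    try:
        types = [str(a.type) for a in u.atoms]
    except (AttributeError, mda.exceptions.NoDataError):
        types = [str(a.name) for a in u.atoms]
    return Trajectory(
        coords=coords,
        ligand_indices=lig.indices.copy(),
        protein_indices=prot.indices.copy(),
        atom_names=[str(a.name) for a in u.atoms],
        atom_types=types,
        frame_interval_ps=frame_interval_ps,
    )


def compute_contact_series(
    traj: Trajectory, cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> ContactSeries:
    """Binary contacts: 1 iff ligand-protein atom distance ≤ cutoff (closed)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    T = traj.n_frames
    values = np.empty((T, traj.n_ligand, traj.n_protein), dtype=np.uint8)
    for t in range(T):
        d = cdist(traj.ligand_coords(t), traj.protein_coords(t))
        values[t] = d <= cutoff
    return ContactSeries(
        values=values,
        cutoff=cutoff,
        ligand_labels=[traj.atom_names[i] for i in traj.ligand_indices],
        protein_labels=[traj.atom_names[i] for i in traj.protein_indices],
        frame_interval_ps=traj.frame_interval_ps,
    )


def aggregate_by_subtype(
    contacts: ContactSeries,
    atom_to_subtype: Mapping[int, int],
    subtype_id: int,
) -> ContactSeries:
    """OR-aggregate the rows of one subtype into a (T, 1, M) series.

    ``atom_to_subtype`` maps ligand-row index (0..N-1) to subtype id; the
    output row is the elementwise max (logical OR) over the subtype's member
    rows, preserving binarity.
    """
    rows = [i for i, s in atom_to_subtype.items() if s == subtype_id]
    if not rows:
        raise LookupError_(f"subtype id {subtype_id} has no ligand atoms")
    agg = contacts.values[:, rows, :].max(axis=1, keepdims=True)
    return ContactSeries(
        values=agg,
        cutoff=contacts.cutoff,
        ligand_labels=[f"subtype_{subtype_id}"],
        protein_labels=list(contacts.protein_labels),
        frame_interval_ps=contacts.frame_interval_ps,
    )


def save_contact_series(contacts: ContactSeries, path) -> None:
    """Write values as compressed .npz plus a JSON sidecar of metadata."""
    path = Path(path)
    np.savez_compressed(path, values=contacts.values)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "cutoff": contacts.cutoff,
                "frame_interval_ps": contacts.frame_interval_ps,
                "ligand_labels": contacts.ligand_labels,
                "protein_labels": contacts.protein_labels,
            }
        )
    )


def load_contact_series(path) -> ContactSeries:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as npz:
        values = npz["values"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return ContactSeries(
        values=values,
        cutoff=meta["cutoff"],
        ligand_labels=meta["ligand_labels"],
        protein_labels=meta["protein_labels"],
        frame_interval_ps=meta["frame_interval_ps"],
    )
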