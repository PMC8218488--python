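"""Synthetic contact systems and toy trajectories with planted ground truth.

MD trajectories of real target-lead complexes are large and usually
proprietary, so every stage of the pipeline is exercised on synthetic data
with known answers:

* contact systems — binary T×N×M contact series assembled from per-subtype
  blocks of ligand atoms. The molecule as a whole occupies a sequence of
  global binding regimes (default: one dominant mode longer than 50 ns and
  one minor mode, mirroring a stable trajectory with a late mode change).
  A *stable* block tracks the molecule: one fixed contact pattern per regime
  plus small Bernoulli flip noise; a *flicker* block re-flips its cells
  every frame at a high rate regardless of regime (the planted "malicious"
  subtype: its contacts never settle); a *switching* block alternates
  between two fixed patterns on its own schedule (a locally bistable
  moiety). The generator also emits the whole-molecule reference assignment
  (frames labelled by global regime) and the planted malicious subtype ids.
* toy trajectories — small PDB topology + multi-model coordinate files with
  a ~12-atom ligand near a pseudo-protein, in one or two alternating poses,
  for exercising trajectory loading and RMSD clustering on real file formats.

Defaults (T=1000 frames, M=128 protein atoms) are chosen to be desk-scale:
large enough for the default minimum cluster size of 50 and the four-layer
encoder, small enough for CPU minutes.

What this emulates — and what it does not: planted blocks reproduce the
*featurized* signature of stable and unstable moieties (persistent vs
churning contact rows), not the physics that causes it; there is no force
field, solvent, or correlated protein motion, and contact noise is
independent per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .clustering import ClusterAssignment
from .contacts import ContactSeries
from .exceptions import ConsistencyError

__all__ = [
    "SubtypeBlock",
    "SyntheticSpec",
    "SyntheticSystem",
    "generate_contact_system",
    "generate_toy_trajectory",
]

DEFAULT_T = 1000
DEFAULT_M = 128


@dataclass(frozen=True)
class SubtypeBlock:
    """One ligand atom subtype in a synthetic system.

    ``behavior`` is ``stable`` (fixed pattern + flip noise), ``flicker``
    (cells re-flip per frame with probability ``flip_rate``) or ``switching``
    (two patterns alternating on the global schedule). ``contact_density``
    is the Bernoulli density of the base pattern(s).
    """

    subtype_id: int
    n_atoms: int = 1
    behavior: str = "stable"
    contact_density: float = 0.3
    flip_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.behavior not in {"stable", "flicker", "switching"}:
            raise ValueError(f"unknown behavior {self.behavior!r}")
        if not (0 <= self.contact_density <= 1 and 0 <= self.flip_rate <= 1):
            raise ValueError("contact_density and flip_rate must lie in [0, 1]")
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be >= 1")


def default_blocks() -> tuple[SubtypeBlock, ...]:
    """Four stable subtypes and one planted high-churn (malicious) subtype."""
    return (
        SubtypeBlock(0, n_atoms=2, behavior="stable"),
        SubtypeBlock(1, n_atoms=2, behavior="stable"),
        SubtypeBlock(2, n_atoms=3, behavior="stable"),
        SubtypeBlock(3, n_atoms=2, behavior="stable"),
        SubtypeBlock(4, n_atoms=2, behavior="flicker", flip_rate=0.5),
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Dimensions, per-subtype blocks and seed of one synthetic system."""

    T: int = DEFAULT_T
    M: int = DEFAULT_M
    blocks: tuple[SubtypeBlock, ...] = field(default_factory=default_blocks)
    seed: int = 0
    regime_changes: tuple[int, ...] = (600,)  # frames where the molecule switches mode
    switch_period: int = 250  # own schedule of "switching" blocks
    frame_interval_ps: float = 100.0  # 1000 frames emulate a 100 ns trajectory

    def __post_init__(self) -> None:
        if self.T < 1 or self.M < 1:
            raise ConsistencyError("T and M must be >= 1")
        if not self.blocks:
            raise ConsistencyError("at least one subtype block is required")
        ids = [b.subtype_id for b in self.blocks]
        if len(set(ids)) != len(ids):
            raise ConsistencyError("subtype ids must be unique")
        if any(not (0 < c < self.T) for c in self.regime_changes):
            raise ConsistencyError("regime changes must lie strictly inside (0, T)")


@dataclass
class SyntheticSystem:
    """Generated contacts plus planted ground truth."""

    contacts: ContactSeries
    atom_to_subtype: dict[int, int]  # ligand row index -> subtype id
    reference: ClusterAssignment  # whole-molecule regime labels
    malicious_subtypes: list[int]
    spec: SyntheticSpec


def generate_contact_system(spec: SyntheticSpec) -> SyntheticSystem:
    """Generate a binary contact series with planted stable/unstable blocks.

    Fully reproducible from ``spec.seed``; the reference assignment labels
    frames by the global regime (constant when no switching block exists,
    otherwise following the switching schedule).
    """
    rng = np.random.default_rng(spec.seed)
    T, M = spec.T, spec.M
    rows = []
    atom_to_subtype: dict[int, int] = {}
    # global binding regime: one label per segment between change points;
    # the molecule as a whole occupies a well-defined mode within a segment
    regime = np.zeros(T, dtype=int)
    for change in sorted(spec.regime_changes):
        regime[change:] += 1
    n_regimes = int(regime.max()) + 1
    own_schedule = (np.arange(T) // spec.switch_period) % 2
    row = 0
    for block in spec.blocks:
        for _ in range(block.n_atoms):
            atom_to_subtype[row] = block.subtype_id
            row += 1
        shape = (block.n_atoms, M)
        if block.behavior == "stable":
            # stable = tracks the molecule's binding mode: one fixed contact
            # pattern per global regime, plus small flip noise
            pats = np.stack(
                [rng.random(shape) < block.contact_density for _ in range(n_regimes)]
            )
            series = pats[regime]
            noise = rng.random((T,) + shape) < block.flip_rate
            series = series ^ noise
        elif block.behavior == "flicker":
            # random-walk churn: each cell flips per frame with flip_rate,
            # independent of the global regime (the planted malicious signal)
            series = np.empty((T,) + shape, dtype=bool)
            series[0] = rng.random(shape) < block.contact_density
            flips = rng.random((T - 1,) + shape) < block.flip_rate
            for t in range(1, T):
                series[t] = series[t - 1] ^ flips[t - 1]
        else:  # switching: alternates two patterns on its own schedule
            pat = np.stack([rng.random(shape) < block.contact_density for _ in range(2)])
            series = pat[own_schedule]
            noise = rng.random((T,) + shape) < block.flip_rate
            series = series ^ noise
        rows.append(series)
    values = np.concatenate(rows, axis=1).astype(np.uint8)
    labels = regime
    contacts = ContactSeries(
        values=values,
        cutoff=4.5,
        ligand_labels=[f"L{i}" for i in range(values.shape[1])],
        protein_labels=[f"P{j}" for j in range(M)],
        frame_interval_ps=spec.frame_interval_ps,
    )
    return SyntheticSystem(
        contacts=contacts,
        atom_to_subtype=atom_to_subtype,
        reference=ClusterAssignment(labels=labels, source="external"),
        malicious_subtypes=[b.subtype_id for b in spec.blocks if b.behavior == "flicker"],
        spec=spec,
    )


def generate_toy_trajectory(
    out_dir,
    n_frames: int = 10,
    two_state: bool = False,
    seed: int = 0,
    jitter: float = 0.05,
) -> tuple[Path, Path]:
    """Write a toy PDB topology + multi-model PDB trajectory.

    A 12-atom ligand (resname LIG) sits near a 120-atom pseudo-protein (40
    glycine-like residues). In ``two_state`` mode the ligand alternates
    between two poses separated by well over 5 Å ligand RMSD, giving exactly
    two binding-mode clusters at the default 2 Å cutoff. Returns
    ``(topology_path, trajectory_path)``.
    """
    import MDAnalysis as mda

    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    n_res = 40
    prot = np.zeros((n_res * 3, 3))
    for r in range(n_res):
        base = np.array([r * 1.5, 10.0 * np.sin(r / 5.0), 10.0 * np.cos(r / 5.0)])
        for a in range(3):
            prot[r * 3 + a] = base + np.array([0.4 * a, 0.3 * (a % 2), 0.0])
    lig0 = rng.normal(loc=[30.0, 0.0, 0.0], scale=1.2, size=(12, 3))
    lig1 = lig0 + np.array([8.0, 6.0, 0.0])  # second pose, far beyond the cutoff

    n_atoms = prot.shape[0] + 12
    u = mda.Universe.empty(
        n_atoms,
        n_residues=n_res + 1,
        atom_resindex=np.concatenate(
            [np.repeat(np.arange(n_res), 3), np.full(12, n_res)]
        ),
        residue_segindex=np.zeros(n_res + 1, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", ["N", "CA", "C"] * n_res + [f"C{i}" for i in range(12)])
    u.add_TopologyAttr("types", ["N", "C", "C"] * n_res + ["CT"] * 12)
    u.add_TopologyAttr("resnames", ["GLY"] * n_res + ["LIG"])
    u.add_TopologyAttr("resids", list(range(1, n_res + 2)))
    u.add_TopologyAttr("elements", ["N", "C", "C"] * n_res + ["C"] * 12)

    top_path = out_dir / "toy_topology.pdb"
    trj_path = out_dir / "toy_trajectory.pdb"
    u.atoms.positions = np.vstack([prot, lig0])
    u.atoms.write(str(top_path))
    with mda.Writer(str(trj_path), n_atoms) as w:
        for t in range(n_frames):
            lig = lig1 if (two_state and t % 2 == 1) else lig0
            pos = np.vstack([prot, lig]) + rng.normal(0.0, jitter, size=(n_atoms, 3))
            u.atoms.positions = pos
            w.write(u.atoms)
    return top_path, trj_path
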