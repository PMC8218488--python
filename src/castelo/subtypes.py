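"""Force-field atom subtyping by Lennard-Jones similarity.

Force fields assign every atom an atom type with nonbonded Lennard-Jones
parameters: a dispersion-energy magnitude ε and a particle-size parameter
(Rmin/2 in CHARMM tables). Atom types whose ε and size lie within a relative
tolerance (default 10%) of each other are grouped into a single "atom
subtype" — the submolecular unit whose contact dynamics the pipeline
analyses. Similarity is a symmetric pairwise test extended by transitive
closure: subtypes are the connected components of the compatibility graph,
which guarantees a partition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .exceptions import FormatError, LookupError_

__all__ = [
    "AtomTypeParams",
    "SubtypeTable",
    "parse_nonbonded_params",
    "group_subtypes",
    "map_ligand_atoms",
]

logger = logging.getLogger(__name__)

#: Section keywords that terminate a NONBONDED block in CHARMM prm/str files.
_SECTION_KEYWORDS = {
    "BONDS", "ANGLES", "DIHEDRALS", "IMPROPER", "IMPROPERS", "CMAP",
    "NBFIX", "HBOND", "NONBONDED", "ATOMS", "END", "RETURN",
}


@dataclass(frozen=True)
class AtomTypeParams:
    """Nonbonded parameters of one force-field atom type.

    ``epsilon`` is stored as a magnitude (kcal/mol, ≥ 0; CHARMM files print it
    negative); ``size`` is the Rmin/2 particle-size parameter (Å, > 0).
    """

    type_name: str
    epsilon: float
    size: float

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be stored as a magnitude (>= 0)")
        if self.size <= 0:
            raise ValueError("size must be positive")


@dataclass
class SubtypeTable:
    """Partition of atom types into subtypes.

    ``subtype_of`` maps each type name to its subtype id; ``members`` maps
    each subtype id to its sorted member type names. IDs are contiguous from 0
    and assigned in a deterministic order (ascending component min-size, then
    min-epsilon, then lexicographically smallest member name).
    """

    subtype_of: dict[str, int] = field(default_factory=dict)
    members: dict[int, list[str]] = field(default_factory=dict)

    @property
    def n_subtypes(self) -> int:
        return len(self.members)

    def to_frame(self, params: Iterable[AtomTypeParams] | None = None) -> pd.DataFrame:
        by_name = {p.type_name: p for p in params} if params else {}
        rows = [
            {
                "type_name": name,
                "epsilon": by_name[name].epsilon if name in by_name else np.nan,
                "size": by_name[name].size if name in by_name else np.nan,
                "subtype_id": sid,
            }
            for name, sid in sorted(self.subtype_of.items())
        ]
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {"subtype_of": self.subtype_of,
             "members": {str(k): v for k, v in self.members.items()}},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SubtypeTable":
        d = json.loads(text)
        return cls(
            subtype_of={k: int(v) for k, v in d["subtype_of"].items()},
            members={int(k): list(v) for k, v in d["members"].items()},
        )


def parse_nonbonded_params(param_text: str) -> list[AtomTypeParams]:
    """Parse the NONBONDED section of CHARMM prm/str dialect text.

    Rows are ``type  ignored  -epsilon  Rmin/2 [1-4 terms ignored]``; epsilon
    is stored as its magnitude. Duplicate type rows: the last occurrence wins
    (a warning is logged). Raises :class:`FormatError` if no NONBONDED section
    is present or a row is non-numeric.
    """
    lines = param_text.splitlines()
    in_section = False
    continuation = False
    records: dict[str, AtomTypeParams] = {}
    found = False
    for raw in lines:
        line = raw.split("!")[0].rstrip()
        if not line.strip():
            continue
        token = line.split()[0].upper()
        if not in_section:
            if token.startswith("NONB"):
                in_section = True
                found = True
                continuation = line.rstrip().endswith("-")
            continue
        if continuation:
            # header options wrapped with trailing '-'
            continuation = line.rstrip().endswith("-")
            continue
        if token in _SECTION_KEYWORDS or token.startswith("NBFIX"):
            in_section = False
            continue
        if token in {"CUTNB", "CTOFNB", "CTONNB", "EPS", "E14FAC", "WMIN"}:
            continue
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f"malformed NONBONDED row: {raw!r}")
        name = parts[0]
        try:
            eps = float(parts[2])
            rmin_half = float(parts[3])
        except ValueError as exc:
            raise FormatError(f"non-numeric NONBONDED row: {raw!r}") from exc
        if name in records:
            logger.warning("duplicate NONBONDED entry for %s; last row wins", name)
        records[name] = AtomTypeParams(name, abs(eps), rmin_half)
    if not found:
        raise FormatError("no NONBONDED section found")
    return list(records.values())


def _compatible(a: AtomTypeParams, b: AtomTypeParams, tol: float) -> bool:
    size_ok = abs(a.size - b.size) <= tol * max(a.size, b.size)
    eps_ok = abs(a.epsilon - b.epsilon) <= tol * max(a.epsilon, b.epsilon)
    return size_ok and eps_ok


def group_subtypes(
    params: list[AtomTypeParams],
    tolerance: float = 0.10,
) -> SubtypeTable:
    """Group atom types into subtypes by LJ similarity.

    Types a, b are compatible iff |size_a − size_b| ≤ tol·max(size) and
    |ε_a − ε_b| ≤ tol·max(ε); subtypes are the connected components of the
    compatibility graph. Output is independent of input row order.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    if not params:
        raise ValueError("params must be non-empty")
    # canonical order so component labelling is order-free
    params = sorted(params, key=lambda p: (p.size, p.epsilon, p.type_name))
    n = len(params)
    sizes = np.array([p.size for p in params])
    epss = np.array([p.epsilon for p in params])
    smax = np.maximum.outer(sizes, sizes)
    emax = np.maximum.outer(epss, epss)
    adj = (np.abs(sizes[:, None] - sizes[None, :]) <= tolerance * smax) & (
        np.abs(epss[:, None] - epss[None, :]) <= tolerance * emax
    )
    _, comp = connected_components(csr_matrix(adj), directed=False)
    groups: dict[int, list[AtomTypeParams]] = {}
    for p, c in zip(params, comp):
        groups.setdefault(int(c), []).append(p)
    keyed = sorted(
        groups.values(),
        key=lambda g: (
            min(p.size for p in g),
            min(p.epsilon for p in g),
            min(p.type_name for p in g),
        ),
    )
    table = SubtypeTable()
    for sid, group in enumerate(keyed):
        names = sorted(p.type_name for p in group)
        table.members[sid] = names
        for name in names:
            table.subtype_of[name] = sid
    return table


def map_ligand_atoms(traj, table: SubtypeTable) -> dict[int, int]:
    """Map each ligand atom index to its subtype id via the atom's type.

    Raises :class:`LookupError_` naming the first force-field type not found
    in ``table``.
    """
    mapping: dict[int, int] = {}
    for idx in traj.ligand_indices:
        type_name = traj.atom_types[idx]
        if type_name not in table.subtype_of:
            raise LookupError_(
                f"atom type {type_name!r} (atom index {idx}) not in subtype table"
            )
        mapping[int(idx)] = table.subtype_of[type_name]
    return mapping
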