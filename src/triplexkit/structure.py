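"""3D containers and PDB I/O.

A :class:`Structure` is a flat, ordered atom table (names, chain ids,
1-based residue indices, Cartesian coordinates in Å) plus per-residue
metadata (base identity, DNA/LNA chemistry, cytosine protonation) mirrored
from the source oligonucleotides.  A :class:`Trajectory` is a shared
topology plus an ``(n_frames, n_atoms, 3)`` coordinate array and a frame
interval in ps.

Chain conventions: ``W`` purine duplex strand, ``C`` pyrimidine duplex
strand, ``T`` third (TFO) strand; residues numbered 1-based, 5'→3' per
chain.  Chemistry survives PDB round trips through residue names: DNA uses
the standard DA/DC/DG/DT (protonated C: DCP), LNA uses LA/LC/LG/LT
(protonated C: LCP).  File-level reading and writing is delegated to
biotite; a pre-scan supplies line-numbered format errors.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "PDBFormatError",
    "Residue",
    "Structure",
    "Trajectory",
    "StructureAssembler",
    "write_pdb",
    "read_pdb",
]


class PDBFormatError(ValueError):
    """Raised for malformed or truncated PDB input."""


RES_NAME_FOR = {
    ("A", "DNA", False): "DA",
    ("C", "DNA", False): "DC",
    ("G", "DNA", False): "DG",
    ("T", "DNA", False): "DT",
    ("C", "DNA", True): "DCP",
    ("A", "LNA", False): "LA",
    ("C", "LNA", False): "LC",
    ("G", "LNA", False): "LG",
    ("T", "LNA", False): "LT",
    ("C", "LNA", True): "LCP",
}
META_FOR_RES_NAME = {v: k for k, v in RES_NAME_FOR.items()}


@dataclass
class Residue:
    """One nucleotide residue: identity plus a contiguous atom-row block."""

    chain: str
    index: int
    base: str
    chemistry: str
    protonated: bool
    start: int  # first atom row
    stop: int  # one past last atom row
    atom_rows: dict[str, int] = field(default_factory=dict)

    @property
    def res_name(self) -> str:
        return RES_NAME_FOR[(self.base, self.chemistry, self.protonated)]

    @property
    def is_purine(self) -> bool:
        return self.base in "AG"


class Structure:
    """Ordered atom table with per-residue metadata.  Coordinates in Å."""

    def __init__(
        self,
        atom_names: list[str],
        coords: np.ndarray,
        residues: list[Residue],
        meta: Optional[dict] = None,
    ):
        self.atom_names = atom_names
        self.coords = np.asarray(coords, dtype=float)
        if self.coords.shape != (len(atom_names), 3):
            raise ValueError("coords shape does not match atom count")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        self.residues = residues
        self.meta = dict(meta or {})
        self._res_index = {(r.chain, r.index): r for r in residues}

    # -- lookups ----------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain not in seen:
                seen.append(r.chain)
        return seen

    def residues_of(self, chain: str) -> list[Residue]:
        return [r for r in self.residues if r.chain == chain]

    def residue(self, chain: str, index: int) -> Residue:
        try:
            return self._res_index[(chain, index)]
        except KeyError:
            raise KeyError(f"no residue {index} in chain {chain!r}") from None

    def atom_row(self, chain: str, index: int, name: str) -> int:
        res = self.residue(chain, index)
        try:
            return res.atom_rows[name]
        except KeyError:
            raise KeyError(
                f"residue {chain}{index} ({res.base}) has no atom {name!r}"
            ) from None

    def has_atom(self, chain: str, index: int, name: str) -> bool:
        return name in self.residue(chain, index).atom_rows

    def xyz(self, chain: str, index: int, name: str) -> np.ndarray:
        return self.coords[self.atom_row(chain, index, name)]

    # -- transforms -------------------------------------------------------
    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Lightweight view sharing topology with new coordinates."""
        new = Structure.__new__(Structure)
        new.atom_names = self.atom_names
        new.coords = np.asarray(coords, dtype=float)
        new.residues = self.residues
        new.meta = self.meta
        new._res_index = self._res_index
        return new

    def copy(self) -> "Structure":
        return self.with_coords(self.coords.copy())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigid motion: x → R x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return self.with_coords(self.coords @ R.T + t)


@dataclass
class Trajectory:
    """Frames of one topology at a fixed sampling interval (ps)."""

    topology: Structure
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval: float = 40.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("trajectory coords must be (n_frames, n_atoms, 3)")
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])

    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


class StructureAssembler:
    """Incremental builder used by the fiber-model code."""

    def __init__(self) -> None:
        self._names: list[str] = []
        self._coords: list[np.ndarray] = []
        self._residues: list[Residue] = []

    def add_residue(
        self,
        chain: str,
        index: int,
        base: str,
        chemistry: str,
        protonated: bool,
        atoms: "dict[str, np.ndarray] | Iterable[tuple[str, np.ndarray]]",
    ) -> None:
        items = atoms.items() if isinstance(atoms, dict) else atoms
        start = len(self._names)
        rows: dict[str, int] = {}
        for name, xyz in items:
            if name in rows:
                raise ValueError(f"duplicate atom {name!r} in residue {chain}{index}")
            rows[name] = len(self._names)
            self._names.append(name)
            self._coords.append(np.asarray(xyz, float))
        self._residues.append(
            Residue(chain, index, base, chemistry, protonated, start, len(self._names), rows)
        )

    def build(self, meta: Optional[dict] = None) -> Structure:
        return Structure(
            self._names, np.array(self._coords, float), self._residues, meta
        )


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

_INTERVAL_REMARK = "REMARK 250 FRAME INTERVAL PS"
_SITE_REMARK = "REMARK 250 TFO SITE START"


def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _to_atom_array(structure: Structure):
    import biotite.structure as bst

    n = structure.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = structure.coords.astype(np.float32)
    chain_ids = np.empty(n, dtype="U4")
    res_ids = np.empty(n, dtype=int)
    res_names = np.empty(n, dtype="U5")
    atom_names = np.array(structure.atom_names, dtype="U6")
    for res in structure.residues:
        chain_ids[res.start : res.stop] = res.chain
        res_ids[res.start : res.stop] = res.index
        res_names[res.start : res.stop] = res.res_name
    arr.chain_id = chain_ids
    arr.res_id = res_ids
    arr.res_name = res_names
    arr.atom_name = atom_names
    arr.element = np.array([_element_of(a) for a in structure.atom_names], dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_pdb(obj: "Structure | Trajectory", path) -> None:
    """Write a Structure (single model) or Trajectory (MODEL/ENDMDL blocks)
    as PDB v3.3.  The frame interval is preserved in a REMARK record."""
    import biotite.structure as bst
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    remarks = []
    if isinstance(obj, Trajectory):
        arr = _to_atom_array(obj.topology)
        stack = bst.stack([arr] * obj.n_frames)
        stack.coord = obj.coords.astype(np.float32)
        pdb.set_structure(stack)
        remarks.append(f"{_INTERVAL_REMARK} {obj.frame_interval:g}")
        meta = obj.topology.meta
    else:
        pdb.set_structure(_to_atom_array(obj))
        meta = obj.meta
    if "tfo_site_start" in meta:
        remarks.append(f"{_SITE_REMARK} {meta['tfo_site_start']}")
    pdb.lines = remarks + pdb.lines
    pdb.write(str(path))


def _prescan(lines: list[str]) -> None:
    n_model = n_endmdl = 0
    saw_atom = False
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            n_model += 1
        elif rec == "ENDMDL":
            n_endmdl += 1
        elif rec in ("ATOM", "HETATM"):
            saw_atom = True
            if len(line.rstrip("\n")) < 54:
                raise PDBFormatError(
                    f"malformed (truncated) ATOM record at line {lineno}"
                )
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBFormatError(
                        f"malformed coordinate field at line {lineno}"
                    ) from None
    if n_model != n_endmdl:
        raise PDBFormatError(
            f"unbalanced MODEL/ENDMDL records ({n_model} vs {n_endmdl}); "
            "file is truncated or malformed"
        )
    if not saw_atom:
        raise PDBFormatError("no ATOM records found")


def read_pdb(path) -> "Structure | Trajectory":
    """Read a PDB file written by :func:`write_pdb` (or any file following
    the chain/residue-name conventions).  Multi-model files return a
    :class:`Trajectory`."""
    from biotite.structure.io.pdb import PDBFile

    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    _prescan(lines)

    interval = 40.0
    meta: dict = {}
    for line in lines:
        if line.startswith(_INTERVAL_REMARK):
            interval = float(line[len(_INTERVAL_REMARK):])
        elif line.startswith(_SITE_REMARK):
            meta["tfo_site_start"] = int(line[len(_SITE_REMARK):])

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)  # AtomArrayStack
    first = stack[0]

    names = [str(a) for a in first.atom_name]
    residues: list[Residue] = []
    current_key: Optional[tuple[str, int]] = None
    for row in range(first.array_length()):
        chain = str(first.chain_id[row])
        idx = int(first.res_id[row])
        key = (chain, idx)
        if key != current_key:
            res_name = str(first.res_name[row])
            if res_name not in META_FOR_RES_NAME:
                raise PDBFormatError(
                    f"unknown residue name {res_name!r} for {chain}{idx}"
                )
            base, chemistry, protonated = META_FOR_RES_NAME[res_name]
            residues.append(
                Residue(chain, idx, base, chemistry, protonated, row, row, {})
            )
            current_key = key
        res = residues[-1]
        name = names[row]
        if name in res.atom_rows:
            raise PDBFormatError(f"duplicate atom {name!r} in residue {chain}{idx}")
        res.atom_rows[name] = row
        res.stop = row + 1

    coords = np.asarray(stack.coord, dtype=float)
    topo = Structure(names, coords[0], residues, meta)
    n_models = sum(1 for l in lines if l[:6].strip() == "MODEL")
    if n_models > 1:
        return Trajectory(topo, coords, frame_interval=interval)
    return topo
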