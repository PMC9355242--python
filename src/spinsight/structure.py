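"""PDB structure reading, residue addressing and in-silico Cys substitution.

Structures are held as flat lists of atoms with author residue numbering,
which is the numbering used for all sites throughout the package.  Parsing
is delegated to :mod:`gemmi`; only model 1 is kept, alternate locations are
resolved to the highest-occupancy conformer (ties: first occurrence) and
waters are dropped by default.
"""

from __future__ import annotations

import math
import urllib.request
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .errors import (
    AddressError,
    FetchError,
    PDBParseError,
    UnsupportedResidueError,
)

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: Side-chain atoms retained after substitution to cysteine.
_BACKBONE_PLUS_CB = {"N", "CA", "C", "O", "CB", "OXT", "H", "HA"}


@dataclass(frozen=True)
class Atom:
    """A single atom with author addressing and Cartesian coordinates in Å."""

    serial: int
    name: str
    residue_name: str
    chain: str
    residue_number: int
    position: np.ndarray
    element: str

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Structure:
    """An ordered collection of atoms addressable by (chain, residue_number)."""

    atoms: list[Atom]
    identifier: str = ""
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("structure must contain at least one atom")
        self._reindex()

    def _reindex(self):
        self._index = {}
        for i, a in enumerate(self.atoms):
            self._index.setdefault((a.chain, a.residue_number), []).append(i)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        seen = []
        for a in self.atoms:
            if a.chain not in seen:
                seen.append(a.chain)
        return seen

    def residue(self, chain: str, residue_number: int) -> list[Atom]:
        """All atoms of one residue; raises AddressError when absent."""
        key = (chain, residue_number)
        if key not in self._index:
            raise AddressError(f"no residue {chain}:{residue_number} in {self.identifier or 'structure'}")
        return [self.atoms[i] for i in self._index[key]]

    def atom(self, chain: str, residue_number: int, name: str) -> Atom:
        for a in self.residue(chain, residue_number):
            if a.name == name:
                return a
        raise AddressError(f"no atom {name} in residue {chain}:{residue_number}")

    def has_residue(self, chain: str, residue_number: int) -> bool:
        return (chain, residue_number) in self._index

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def heavy_positions(self, exclude_residue: tuple[str, int] | None = None) -> np.ndarray:
        """Coordinates of non-hydrogen atoms, optionally skipping one residue."""
        pts = [
            a.position
            for a in self.atoms
            if not a.is_hydrogen
            and (exclude_residue is None or (a.chain, a.residue_number) != exclude_residue)
        ]
        return np.array(pts).reshape(-1, 3)

    def to_pdb(self) -> str:
        """Serialize as fixed-column ATOM records (single model, no TER logic)."""
        lines = []
        if self.identifier:
            lines.append(f"HEADER    {self.identifier}")
        for i, a in enumerate(self.atoms, start=1):
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            x, y, z = a.position
            lines.append(
                f"ATOM  {i:5d} {name}{'':1s}{a.residue_name:>3s} {a.chain[:1]:1s}"
                f"{a.residue_number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}"
            )
        lines.append("END")
        return "\n".join(lines) + "\n"


def read_structure(pdb_text: str, identifier: str = "", include_waters: bool = False) -> Structure:
    """Parse PDB text into a :class:`Structure`.

    Only the first model is read; alternate locations are resolved to the
    highest-occupancy copy (ties broken by first occurrence); waters are
    excluded unless requested.
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"could not parse PDB text: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError("no ATOM/HETATM records found in input")
    model = st[0]
    atoms: list[Atom] = []
    serial = 0
    for chain in model:
        for res in chain:
            if not include_waters and res.name in _WATER_NAMES:
                continue
            # altloc resolution: highest occupancy wins, first occurrence breaks ties
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            for at in res:  # preserve file order of first occurrences
                if best.get(at.name) is not at:
                    continue
                serial += 1
                atoms.append(
                    Atom(
                        serial=serial,
                        name=at.name,
                        residue_name=res.name,
                        chain=chain.name,
                        residue_number=res.seqid.num,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        element=at.element.name or "X",
                    )
                )
    if not atoms:
        raise PDBParseError("no ATOM/HETATM records found in input")
    return Structure(atoms=atoms, identifier=identifier or st.name)


def fetch_pdb(pdb_id: str, timeout: float = 15.0) -> Structure:
    """Download a PDB entry from RCSB and parse it.

    Raises :class:`FetchError` when the entry cannot be retrieved (e.g. in
    offline environments).
    """
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            text = resp.read().decode("utf-8", errors="replace")
    except Exception as exc:
        raise FetchError(f"could not retrieve PDB entry {pdb_id} from {url}: {exc}") from exc
    return read_structure(text, identifier=pdb_id.upper())


def substitute_to_cys(structure: Structure, chain: str, residue_number: int) -> Structure:
    """Return a copy with one residue truncated past CB and renamed CYS.

    The residue must have backbone atoms N, CA, C and a CB; glycine (no CB)
    is rejected.  Backbone coordinates are carried over bit-identically.
    """
    res_atoms = structure.residue(chain, residue_number)
    names = {a.name for a in res_atoms}
    if res_atoms[0].residue_name == "GLY" or "CB" not in names:
        raise UnsupportedResidueError(
            f"residue {chain}:{residue_number} ({res_atoms[0].residue_name}) has no CB; "
            "cannot model a cysteine there"
        )
    missing = {"N", "CA", "C"} - names
    if missing:
        raise UnsupportedResidueError(
            f"residue {chain}:{residue_number} lacks backbone atoms {sorted(missing)}"
        )
    new_atoms = []
    for a in structure.atoms:
        if (a.chain, a.residue_number) == (chain, residue_number):
            if a.name not in _BACKBONE_PLUS_CB:
                continue
            a = replace(a, residue_name="CYS")
        new_atoms.append(a)
    return Structure(atoms=new_atoms, identifier=structure.identifier)


def atom_distance(
    structure: Structure,
    a: tuple[str, int, str],
    b: tuple[str, int, str],
) -> float:
    """Euclidean distance in Å between two addressed atoms."""
    pa = structure.atom(*a).position
    pb = structure.atom(*b).position
    return float(math.dist(pa, pb))
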