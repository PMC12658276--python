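"""Structure containers, PDB/PQR input, titratable-site detection and distances.

The in-memory unit is the :class:`StructureFrame`: a flat list of atoms
with coordinates (Å), partial charges (e) and radii (Å), which is exactly
what the finite-difference electrostatics needs.  Multi-frame ensembles
(snapshots of one short trajectory) are grouped in :class:`FrameEnsemble`.

PQR files are read and written in a whitespace dialect that always
carries a chain column::

    ATOM serial name resname chain resid x y z charge radius

PDB files carry no charges/radii; those are filled in from a
user-overridable YAML parameter table (radii per element, charges per
residue/atom for the default protonation form).
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParameterLookupError, ParseError

logger = logging.getLogger(__name__)

# Residues that titrate in the physiological range, with the reference
# (model-compound, bulk water) pKa of each.
REFERENCE_PKAS: dict[str, float] = {
    "ASP": 3.90,
    "GLU": 4.07,
    "HIS": 6.04,
    "LYS": 10.54,
}

# Atom on which the +-1 proton charge is localized per residue class.
# The charge sets are data (drop-in replaceable), not code.
DEFAULT_CHARGE_SETS: dict[str, dict[str, dict[str, float]]] = {
    "ASP": {"protonated": {"CG": 0.0}, "deprotonated": {"CG": -1.0}},
    "GLU": {"protonated": {"CD": 0.0}, "deprotonated": {"CD": -1.0}},
    # Neutral His is the "deprotonated" member of the pair; the +1 form
    # spreads over both ring nitrogens.
    "HIS": {
        "protonated": {"ND1": 0.5, "NE2": 0.5},
        "deprotonated": {"ND1": 0.0, "NE2": 0.0},
    },
    "LYS": {"protonated": {"NZ": 1.0}, "deprotonated": {"NZ": 0.0}},
}

# Default protonation form of each residue class (round-1 assignment of
# the iterative protocol): acids deprotonated, His neutral, Lys charged.
DEFAULT_FORM: dict[str, str] = {
    "ASP": "deprotonated",
    "GLU": "deprotonated",
    "HIS": "deprotonated",
    "LYS": "protonated",
}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "H", "HA", "HN", "H1", "H2", "H3"}

ION_VALENCE: dict[str, float] = {
    "NA": 1.0,
    "SOD": 1.0,
    "K": 1.0,
    "POT": 1.0,
    "CL": -1.0,
    "CLA": -1.0,
    "CA": 2.0,
    "CAL": 2.0,
    "MG": 2.0,
    "MGA": 2.0,
}

LIPID_RESNAMES = {"LIP", "POPC", "POPE", "DPPC", "MEMB"}

_ELEMENT_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "NA": 1.36,
    "CL": 1.81,
    "K": 1.76,
    "CA": 1.37,
    "MG": 1.18,
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, position (Å), partial charge (e) and radius (Å)."""

    atom_name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    position: np.ndarray
    partial_charge: float
    radius: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", pos)
        if self.radius < 0:
            raise ValueError("radius must be non-negative")
        if not self.chain_id:
            raise ValueError("chain_id must be non-empty")

    @property
    def key(self) -> tuple[str, int, str]:
        """Unique identifier of the atom within a frame."""
        return (self.chain_id, self.residue_id, self.atom_name)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass
class StructureFrame:
    """One ensemble snapshot: a sequence of atoms plus a label."""

    atoms: list[AtomRecord]
    frame_label: str = ""
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError("a StructureFrame requires at least one atom")
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(f"duplicate atom identifier in frame: {dup}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def select(self, predicate: Callable[[AtomRecord], bool]) -> list[AtomRecord]:
        return [a for a in self.atoms if predicate(a)]

    def residue_atoms(self, chain_id: str, residue_id: int) -> list[AtomRecord]:
        return [a for a in self.atoms if a.chain_id == chain_id and a.residue_id == residue_id]

    def atom_keys(self) -> list[tuple[str, int, str]]:
        return [a.key for a in self.atoms]

    def is_ion(self, atom: AtomRecord) -> bool:
        return atom.residue_name.upper() in ION_VALENCE

    def is_lipid(self, atom: AtomRecord) -> bool:
        return atom.residue_name.upper() in LIPID_RESNAMES

    def protein_atoms(self, include_hydrogens: bool = False) -> list[AtomRecord]:
        """Atoms that belong to the polymer (not ions, not lipid markers)."""
        out = []
        for a in self.atoms:
            if self.is_ion(a) or self.is_lipid(a):
                continue
            if not include_hydrogens and a.is_hydrogen:
                continue
            out.append(a)
        return out

    def with_charges(self, charge_map: Mapping[tuple[str, int, str], float]) -> "StructureFrame":
        """Copy of the frame with the listed atom charges replaced."""
        atoms = [
            replace(a, partial_charge=charge_map.get(a.key, a.partial_charge))
            for a in self.atoms
        ]
        return StructureFrame(atoms=atoms, frame_label=self.frame_label, box=self.box)


@dataclass
class FrameEnsemble:
    """A set of topologically identical frames for one conformational state."""

    frames: list[StructureFrame]
    state_label: str = "closed"

    def __post_init__(self) -> None:
        if self.state_label not in {"closed", "open", "desensitized"}:
            raise ValueError(f"unknown state label {self.state_label!r}")
        if not self.frames:
            raise ValueError("ensemble requires at least one frame")
        ref = self.frames[0].atom_keys()
        for f in self.frames[1:]:
            if f.atom_keys() != ref:
                raise ValueError(
                    f"frame {f.frame_label!r} does not share the ensemble topology"
                )

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class TitratableSite:
    """A protonatable side chain and its two charge sets.

    ``charge_sets`` maps state ('protonated'/'deprotonated') to per-atom
    partial charges for the titratable functional group.  The two sets
    must differ by exactly +1 e (protonated minus deprotonated).
    """

    residue_name: str
    residue_id: int
    chain_id: str
    reference_pka: float
    charge_sets: Mapping[str, Mapping[str, float]] = field(hash=False)

    def __post_init__(self) -> None:
        if self.residue_name not in REFERENCE_PKAS:
            raise ValueError(f"{self.residue_name} is not a titratable residue type")
        dq = sum(self.charge_sets["protonated"].values()) - sum(
            self.charge_sets["deprotonated"].values()
        )
        if not math.isclose(dq, 1.0, abs_tol=1e-9):
            raise ValueError(
                f"charge sets must differ by +1 e (protonated - deprotonated), got {dq}"
            )

    @property
    def site_id(self) -> str:
        return f"{self.chain_id}:{self.residue_name}{self.residue_id}"

    @property
    def default_form(self) -> str:
        return DEFAULT_FORM[self.residue_name]

    def charge_map(self, state: str) -> dict[tuple[str, int, str], float]:
        """Atom-key -> charge map realizing the given protonation state."""
        return {
            (self.chain_id, self.residue_id, name): q
            for name, q in self.charge_sets[state].items()
        }


@dataclass
class ProtonationAssignment:
    """Current protonated/deprotonated state of every titratable site."""

    states: dict[str, str]

    def __post_init__(self) -> None:
        for sid, st in self.states.items():
            if st not in {"protonated", "deprotonated"}:
                raise ValueError(f"invalid state {st!r} for site {sid}")

    def copy(self) -> "ProtonationAssignment":
        return ProtonationAssignment(states=dict(self.states))

    def __getitem__(self, site_id: str) -> str:
        return self.states[site_id]

    @classmethod
    def default_for(cls, sites: Sequence[TitratableSite]) -> "ProtonationAssignment":
        """Round-1 assignment: acids/His in default neutral-acid form, Lys protonated."""
        return cls(states={s.site_id: s.default_form for s in sites})


def apply_assignment(
    frame: StructureFrame,
    sites: Sequence[TitratableSite],
    assignment: ProtonationAssignment,
) -> StructureFrame:
    """Frame with every site's functional-group charges set per the assignment."""
    charge_map: dict[tuple[str, int, str], float] = {}
    for site in sites:
        if site.site_id not in assignment.states:
            raise KeyError(f"site {site.site_id} missing from assignment")
        charge_map.update(site.charge_map(assignment[site.site_id]))
    return frame.with_charges(charge_map)


# ---------------------------------------------------------------------------
# reading / writing


def _default_parameter_table() -> dict:
    path = Path(__file__).parent / "data" / "pdb_parameters.yaml"
    with open(path) as fh:
        return yaml.safe_load(fh)


def _guess_element(atom_name: str, residue_name: str) -> str:
    name = atom_name.strip()
    if residue_name.upper() in ION_VALENCE and name.upper() in _ELEMENT_RADII:
        return name.upper()
    # strip leading digits (e.g. 1HB), take leading alpha character(s)
    stripped = name.lstrip("0123456789")
    if not stripped:
        return name
    if stripped[:2].upper() in {"CL", "NA", "MG"} and len(name) <= 2:
        return stripped[:2].upper()
    return stripped[0].upper()


def read_structure(
    path: str | Path,
    dialect: str,
    parameter_table: Mapping | None = None,
) -> StructureFrame:
    """Read one structure file into a :class:`StructureFrame`.

    Parameters
    ----------
    path:
        Input file.
    dialect:
        ``"pqr"`` (whitespace dialect with chain column; charges and radii
        from the file) or ``"pdb"`` (charges/radii assigned from
        ``parameter_table``, default the packaged table).
    parameter_table:
        Optional override of the PDB charge/radius parameter table with
        keys ``radii`` (element -> Å) and ``charges``
        (residue -> atom -> e).
    """
    path = Path(path)
    if dialect == "pqr":
        return _read_pqr(path)
    if dialect == "pdb":
        return _read_pdb(path, parameter_table)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_pqr(path: Path) -> StructureFrame:
    atoms: list[AtomRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("REMARK", "COMMENT", "#", "END", "TER")):
                continue
            fields = line.split()
            if fields[0] not in {"ATOM", "HETATM"}:
                raise ParseError(f"{path}:{lineno}: unexpected record {fields[0]!r}")
            try:
                if len(fields) == 11:
                    (_, _serial, name, resname, chain, resid, x, y, z, q, r) = fields
                elif len(fields) == 10:
                    # chain column omitted (plain PQR); default chain A
                    (_, _serial, name, resname, resid, x, y, z, q, r) = fields
                    chain = "A"
                else:
                    raise ValueError(f"expected 10 or 11 fields, got {len(fields)}")
                atoms.append(
                    AtomRecord(
                        atom_name=name,
                        element=_guess_element(name, resname),
                        residue_name=resname,
                        residue_id=int(resid),
                        chain_id=chain,
                        position=np.array([float(x), float(y), float(z)]),
                        partial_charge=float(q),
                        radius=float(r),
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed PQR record ({exc})") from exc
    if not atoms:
        raise ParseError(f"{path}: no atoms found")
    return StructureFrame(atoms=atoms, frame_label=path.stem)


def _read_pdb(path: Path, parameter_table: Mapping | None) -> StructureFrame:
    from Bio.PDB import PDBParser

    table = dict(parameter_table) if parameter_table is not None else _default_parameter_table()
    radii: Mapping[str, float] = table.get("radii", {})
    charges: Mapping[str, Mapping[str, float]] = table.get("charges", {})

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Bio.PDB raises bare exceptions on bad input
        raise ParseError(f"{path}: could not parse PDB file ({exc})") from exc

    atoms: list[AtomRecord] = []
    model = next(structure.get_models())
    for chain in model:
        chain_id = chain.id.strip() or "A"
        for residue in chain:
            resname = residue.get_resname().strip()
            resid = residue.get_id()[1]
            for atom in residue:
                name = atom.get_name()
                element = (atom.element or _guess_element(name, resname)).upper()
                if element not in radii:
                    raise ParameterLookupError(
                        f"no radius for element {element!r} "
                        f"(atom {chain_id}:{resname}{resid}:{name})"
                    )
                charge = float(charges.get(resname, {}).get(name, 0.0))
                atoms.append(
                    AtomRecord(
                        atom_name=name,
                        element=element,
                        residue_name=resname,
                        residue_id=resid,
                        chain_id=chain_id,
                        position=np.round(atom.get_coord().astype(float), 3),
                        partial_charge=charge,
                        radius=float(radii[element]),
                    )
                )
    if not atoms:
        raise ParseError(f"{path}: no atoms found")
    return StructureFrame(atoms=atoms, frame_label=path.stem)


def write_pqr(frame: StructureFrame, path: str | Path) -> None:
    """Write the frame in the whitespace PQR dialect (with chain column)."""
    with open(path, "w") as fh:
        for i, a in enumerate(frame.atoms, start=1):
            x, y, z = a.position
            fh.write(
                f"ATOM {i} {a.atom_name} {a.residue_name} {a.chain_id} {a.residue_id} "
                f"{x:.3f} {y:.3f} {z:.3f} {a.partial_charge:.4f} {a.radius:.4f}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# titratable sites


def identify_titratable_sites(
    frame: StructureFrame,
    include: Iterable[str] | None = None,
    reference_pkas: Mapping[str, float] | None = None,
    charge_sets: Mapping[str, Mapping[str, Mapping[str, float]]] | None = None,
) -> list[TitratableSite]:
    """All Asp/Glu/His/Lys sites of the frame, in (chain, residue) order.

    Residues whose functional-group atoms (the charge-set atoms) are
    missing are skipped with a warning rather than raising, mirroring how
    incomplete side chains are handled in practice.
    """
    if include is None:
        include = set(REFERENCE_PKAS)
    include = {r.upper() for r in include}
    unknown = include - set(REFERENCE_PKAS)
    if unknown:
        raise ValueError(f"non-titratable residue names in include set: {sorted(unknown)}")
    ref = dict(REFERENCE_PKAS)
    if reference_pkas:
        ref.update(reference_pkas)
    csets = charge_sets if charge_sets is not None else DEFAULT_CHARGE_SETS

    seen: dict[tuple[str, int], str] = {}
    atom_names: dict[tuple[str, int], set[str]] = {}
    for a in frame.atoms:
        rk = (a.chain_id, a.residue_id)
        if a.residue_name.upper() in include:
            seen.setdefault(rk, a.residue_name.upper())
            atom_names.setdefault(rk, set()).add(a.atom_name)

    sites: list[TitratableSite] = []
    for (chain, resid) in sorted(seen):
        resname = seen[(chain, resid)]
        needed = set(csets[resname]["protonated"]) | set(csets[resname]["deprotonated"])
        if not needed <= atom_names[(chain, resid)]:
            missing = sorted(needed - atom_names[(chain, resid)])
            logger.warning(
                "skipping %s:%s%d: missing side-chain atoms %s", chain, resname, resid, missing
            )
            warnings.warn(
                f"skipping {chain}:{resname}{resid}: missing side-chain atoms {missing}",
                stacklevel=2,
            )
            continue
        sites.append(
            TitratableSite(
                residue_name=resname,
                residue_id=resid,
                chain_id=chain,
                reference_pka=ref[resname],
                charge_sets=csets[resname],
            )
        )
    return sites


# ---------------------------------------------------------------------------
# distances


def _sidechain_heavy_atoms(frame: StructureFrame, chain_id: str, residue_id: int) -> list[AtomRecord]:
    # side chain = all non-hydrogen atoms past and including C-beta
    return [
        a
        for a in frame.residue_atoms(chain_id, residue_id)
        if not a.is_hydrogen and a.atom_name.upper() not in BACKBONE_ATOMS
    ]


def _parse_residue_identifier(ident) -> tuple[str, int]:
    if isinstance(ident, tuple):
        return str(ident[0]), int(ident[1])
    chain, _, rest = str(ident).partition(":")
    digits = "".join(ch for ch in rest if ch.isdigit() or ch == "-")
    if not digits:
        raise ValueError(f"cannot parse residue identifier {ident!r}")
    return chain, int(digits)


def min_sidechain_distance(frame: StructureFrame, residue_a, residue_b) -> float:
    """Minimum distance (Å) between heavy side-chain atoms of two residues.

    Residue identifiers are ``(chain, resid)`` tuples or strings like
    ``"A:73"`` / ``"A:HIS73"``.  Side-chain atoms are all non-hydrogen
    atoms past (and including) C-beta.
    """
    ca, ra = _parse_residue_identifier(residue_a)
    cb, rb = _parse_residue_identifier(residue_b)
    atoms_a = _sidechain_heavy_atoms(frame, ca, ra)
    atoms_b = _sidechain_heavy_atoms(frame, cb, rb)
    for label, atoms in ((residue_a, atoms_a), (residue_b, atoms_b)):
        if not atoms:
            raise ValueError(f"residue {label!r} has no heavy side-chain atoms")
    pa = np.array([a.position for a in atoms_a])
    pb = np.array([a.position for a in atoms_b])
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    return float(d.min())


# ---------------------------------------------------------------------------
# table export


def export_table(records, path: str | Path) -> None:
    """Write a result table as UTF-8 CSV with header and stable column order."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records))
    if df.empty:
        raise ValueError("refusing to export an empty table")
    df.to_csv(path, index=False, encoding="utf-8")
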