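"""Per-frame membrane geometry and explicit-ion selection.

The implicit-membrane dielectric model needs, for every frame, the slab
midplane and thickness.  Both are estimated from marker atoms: the bilayer
midplane from the z-coordinates of the terminal methyl groups of the lipid
tails, and the total thickness from the mean phosphorus z of the two
leaflets.  A fixed-thickness headgroup shell (default 2 Å) sits at each
core boundary.

Mobile ions caught near the protein in a snapshot interact too strongly to
be absorbed into mean-field Debye screening, so they enter the calculation
as explicit charges: monovalent ions within 3 Å of the protein, divalent
ions within 6 Å (defaults; both configurable).
"""
from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import GeometryError, IonClassificationError
from .structure_io import ION_VALENCE, AtomRecord, StructureFrame

DEFAULT_HEADGROUP_THICKNESS = 2.0
DEFAULT_ION_THRESHOLDS = {1: 3.0, 2: 6.0}
DEFAULT_PHOSPHORUS_PATTERNS = ("P", "P8", "P31")
DEFAULT_METHYL_PATTERNS = ("C216", "C316", "C?16")


@dataclass(frozen=True)
class MembraneGeometry:
    """Slab model of one frame's membrane (all lengths in Å)."""

    midplane_z: float
    core_half_thickness: float
    total_thickness: float
    headgroup_thickness: float = DEFAULT_HEADGROUP_THICKNESS

    def __post_init__(self) -> None:
        if self.total_thickness <= 0:
            raise GeometryError("total membrane thickness must be positive")
        if self.core_half_thickness + self.headgroup_thickness > self.total_thickness / 2 + 1e-6:
            raise GeometryError("core + headgroup exceed half the total thickness")

    def region_of_z(self, z: np.ndarray) -> np.ndarray:
        """0 = solvent, 1 = headgroup shell, 2 = hydrophobic core."""
        dz = np.abs(np.asarray(z, dtype=float) - self.midplane_z)
        out = np.zeros(dz.shape, dtype=np.uint8)
        out[dz < self.core_half_thickness + self.headgroup_thickness] = 1
        out[dz < self.core_half_thickness] = 2
        return out


@dataclass
class IonSelection:
    """Explicit ions retained for the electrostatic calculation."""

    ions: list[tuple[str, float, np.ndarray, float]]  # (species, valence, position, distance)
    thresholds: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_ION_THRESHOLDS))

    def __len__(self) -> int:
        return len(self.ions)

    @property
    def positions(self) -> np.ndarray:
        if not self.ions:
            return np.zeros((0, 3))
        return np.array([p for (_, _, p, _) in self.ions])

    @property
    def charges(self) -> np.ndarray:
        return np.array([z for (_, z, _, _) in self.ions])


def _pattern_predicate(patterns: Sequence[str]) -> Callable[[AtomRecord], bool]:
    def pred(atom: AtomRecord) -> bool:
        return any(fnmatch.fnmatchcase(atom.atom_name.upper(), p.upper()) for p in patterns)

    return pred


def has_membrane(frame: StructureFrame,
                 phosphorus_selector: Callable[[AtomRecord], bool] | None = None,
                 terminal_methyl_selector: Callable[[AtomRecord], bool] | None = None) -> bool:
    """True when the frame carries both phosphorus and terminal-methyl markers."""
    p_sel = phosphorus_selector or _pattern_predicate(DEFAULT_PHOSPHORUS_PATTERNS)
    m_sel = terminal_methyl_selector or _pattern_predicate(DEFAULT_METHYL_PATTERNS)
    lipid = [a for a in frame.atoms if frame.is_lipid(a)]
    return any(p_sel(a) for a in lipid) and any(m_sel(a) for a in lipid)


def estimate_membrane_geometry(
    frame: StructureFrame,
    phosphorus_selector: Callable[[AtomRecord], bool] | None = None,
    terminal_methyl_selector: Callable[[AtomRecord], bool] | None = None,
    headgroup_thickness: float = DEFAULT_HEADGROUP_THICKNESS,
) -> MembraneGeometry:
    """Estimate midplane and thickness from lipid marker atoms.

    midplane_z is the mean z of the terminal methyl atoms; the total
    thickness is the difference of the leaflet-mean phosphorus z values,
    leaflets being P atoms above/below the methyl midplane.
    """
    p_sel = phosphorus_selector or _pattern_predicate(DEFAULT_PHOSPHORUS_PATTERNS)
    m_sel = terminal_methyl_selector or _pattern_predicate(DEFAULT_METHYL_PATTERNS)

    lipid_atoms = [a for a in frame.atoms if frame.is_lipid(a)]
    p_z = np.array([a.position[2] for a in lipid_atoms if p_sel(a)])
    m_z = np.array([a.position[2] for a in lipid_atoms if m_sel(a)])
    if m_z.size == 0:
        raise GeometryError("terminal-methyl selector matched no atoms")
    if p_z.size == 0:
        raise GeometryError("phosphorus selector matched no atoms")

    midplane = float(m_z.mean())
    upper = p_z[p_z > midplane]
    lower = p_z[p_z <= midplane]
    if upper.size == 0 or lower.size == 0:
        raise GeometryError("all phosphorus atoms lie on one side of the methyl midplane")

    total = float(upper.mean() - lower.mean())
    core_half = total / 2.0 - headgroup_thickness
    if core_half <= 0:
        raise GeometryError(
            f"membrane too thin ({total:.2f} Å) for a {headgroup_thickness} Å headgroup shell"
        )
    return MembraneGeometry(
        midplane_z=midplane,
        core_half_thickness=core_half,
        total_thickness=total,
        headgroup_thickness=headgroup_thickness,
    )


def select_explicit_ions(
    frame: StructureFrame,
    protein_atoms: Sequence[AtomRecord] | None = None,
    thresholds: Mapping[int, float] | None = None,
    ion_valences: Mapping[str, float] | None = None,
) -> IonSelection:
    """Retain ions whose minimum distance to a protein heavy atom is below
    the threshold for their valence class.

    Distances are minima over all protein heavy atoms; the per-valence-class
    thresholds default to 3 Å (monovalent) and 6 Å (divalent).
    """
    thresholds = dict(thresholds or DEFAULT_ION_THRESHOLDS)
    # a user-supplied valence table is authoritative: species recognized
    # as ionic but absent from it are a classification error
    valences = (
        {k.upper(): v for k, v in ion_valences.items()}
        if ion_valences is not None
        else dict(ION_VALENCE)
    )
    ion_atoms = [a for a in frame.atoms if frame.is_ion(a) or a.residue_name.upper() in valences]
    for a in ion_atoms:
        if a.residue_name.upper() not in valences:
            raise IonClassificationError(f"unknown ion species {a.residue_name!r}")

    if protein_atoms is None:
        protein_atoms = frame.protein_atoms(include_hydrogens=False)
    if not protein_atoms:
        raise GeometryError("no protein atoms available for ion-distance computation")

    tree = cKDTree(np.array([a.position for a in protein_atoms]))
    retained: list[tuple[str, float, np.ndarray, float]] = []
    for a in ion_atoms:
        valence = valences[a.residue_name.upper()]
        vclass = int(round(abs(valence)))
        if vclass not in thresholds:
            raise IonClassificationError(
                f"no distance threshold configured for |z| = {vclass} ({a.residue_name})"
            )
        dist, _ = tree.query(a.position)
        if dist < thresholds[vclass]:
            retained.append((a.residue_name.upper(), valence, a.position.copy(), float(dist)))
    return IonSelection(ions=retained, thresholds=thresholds)
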