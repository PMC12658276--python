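"""Per-site pKa from the Poisson-Boltzmann thermodynamic cycle.

The pKa of a titratable side chain in the protein is obtained by
comparing the electrostatic work of deprotonation in the protein with
that of the same group excised into bulk water (the model compound):

    pKa = pKa_ref + ( [G_deprot - G_prot]_protein
                    - [G_deprot - G_prot]_water ) / (ln 10 · kBT)

An environment that makes deprotonation harder than in water raises the
pKa; one that stabilizes the deprotonated form lowers it.  Both legs of
the cycle are computed on identical grids at identical spacings so the
spurious grid self-energy of the spread point charges cancels in the
double difference.

The model compound is the residue's side chain capped at C-alpha: the
same atoms at the same coordinates, all charges zeroed except the
titratable functional group, solvated with its own cavity in solvent
dielectric, without membrane or explicit ions.

Ensemble averaging follows the frames-times-subunits scheme: the
reported estimate is the mean ± SD over every (frame, equivalent
subunit site) sample, e.g. n = 5 frames × 3 subunits = 15.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import PhysicalConstants
from .environment_model import (
    MembraneGeometry,
    IonSelection,
    estimate_membrane_geometry,
    has_membrane,
    select_explicit_ions,
)
from .errors import SolverError
from .pb_solver import (
    DEFAULT_REGION_VALUES,
    GridSpec,
    electrostatic_free_energy,
    focused_solve,
)
from .structure_io import (
    FrameEnsemble,
    ProtonationAssignment,
    StructureFrame,
    TitratableSite,
    apply_assignment,
)

logger = logging.getLogger(__name__)


@dataclass
class SolverSettings:
    """Grid and dielectric settings shared by every cycle leg."""

    coarse_spacing: float = 1.5
    fine_spacing: float = 0.5
    padding: float = 10.0
    focus_half_extent: float = 8.0
    region_values: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_VALUES)
    )
    tol: float = 1e-6
    maxiter: int = 10000


@dataclass
class FrameEnvironment:
    """Everything the solver needs about one frame beyond the protein."""

    membrane: MembraneGeometry | None
    ions: IonSelection


def build_environment(
    frame: StructureFrame,
    ion_thresholds: Mapping[int, float] | None = None,
    headgroup_thickness: float = 2.0,
) -> FrameEnvironment:
    """Estimate membrane geometry (if markers present) and select ions."""
    membrane = None
    if has_membrane(frame):
        membrane = estimate_membrane_geometry(frame, headgroup_thickness=headgroup_thickness)
    ions = select_explicit_ions(frame, thresholds=ion_thresholds)
    return FrameEnvironment(membrane=membrane, ions=ions)


@dataclass
class PKaEstimate:
    """Ensemble pKa of one site: mean ± SD over frame×subunit samples."""

    site_id: str
    residue_name: str
    mean_pka: float
    sd: float
    n: int
    samples: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.samples and not (
            min(self.samples) - 1e-9 <= self.mean_pka <= max(self.samples) + 1e-9
        ):
            raise ValueError("mean outside the sample range")


@dataclass
class StatePKaTable:
    """Per-site ensemble pKa estimates for one conformational state."""

    state: str
    estimates: dict[str, PKaEstimate]
    round_index: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid, est in sorted(self.estimates.items()):
            row = {
                "state": self.state,
                "site": sid,
                "residue_name": est.residue_name,
                "mean_pka": est.mean_pka,
                "sd": est.sd,
                "n": est.n,
            }
            for i, v in enumerate(est.samples):
                row[f"sample_{i}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cycle legs


def _site_fine_grid(center: np.ndarray, settings: SolverSettings) -> GridSpec:
    """Fine grid centered on the site, shared by every leg of its cycle.

    Pinning one lattice across legs makes the grid self-energy of the
    spread site charges cancel exactly in the double difference; this
    requires ``focus_half_extent <= padding`` so the fine box stays
    inside each leg's coarse grid.
    """
    if settings.focus_half_extent > settings.padding:
        raise ValueError("focus_half_extent must not exceed the coarse-grid padding")
    half = settings.focus_half_extent
    n = int(math.ceil(2.0 * half / settings.fine_spacing - 1e-9)) + 1
    return GridSpec(origin=np.asarray(center) - half, spacing=settings.fine_spacing, dims=(n, n, n))


def _leg_energy(
    frame: StructureFrame,
    membrane: MembraneGeometry | None,
    extra_positions: np.ndarray,
    extra_charges: np.ndarray,
    fine_grid: GridSpec,
    constants: PhysicalConstants,
    settings: SolverSettings,
    region_values: Mapping[str, float],
) -> float:
    """½Σqφ for the frame's charges plus extra (ion) charges."""
    positions = frame.positions
    charges = frame.charges
    if len(extra_positions):
        positions = np.vstack([positions, extra_positions])
        charges = np.concatenate([charges, extra_charges])
    nonzero = charges != 0.0
    if not nonzero.any():
        return 0.0
    fine, coarse = focused_solve(
        positions[nonzero],
        charges[nonzero],
        frame,
        membrane,
        constants,
        coarse_spacing=settings.coarse_spacing,
        fine_spacing=settings.fine_spacing,
        padding=settings.padding,
        fine_grid=fine_grid,
        region_values=region_values,
        tol=settings.tol,
        maxiter=settings.maxiter,
    )
    pts = positions[nonzero]
    q = charges[nonzero]
    in_fine = fine.grid.contains(pts)
    energy = 0.0
    if in_fine.any():
        energy += 0.5 * float(np.sum(q[in_fine] * fine.interpolate(pts[in_fine])))
    if (~in_fine).any():
        energy += 0.5 * float(np.sum(q[~in_fine] * coarse.interpolate(pts[~in_fine])))
    return energy


def _model_compound_frame(frame: StructureFrame, site: TitratableSite) -> StructureFrame:
    """The site's residue excised at C-alpha with all non-site charges zeroed.

    Geometry (and hence the cavity) is identical to the residue in the
    frame; only the titratable functional-group atoms carry charge, set
    later per state.
    """
    atoms = frame.residue_atoms(site.chain_id, site.residue_id)
    keep = [a for a in atoms if a.atom_name.upper() not in {"N", "C", "O", "OXT"}]
    zeroed = {a.key: 0.0 for a in keep}
    sub = StructureFrame(atoms=list(keep), frame_label=f"{frame.frame_label}|model")
    return sub.with_charges(zeroed)


def _site_center(frame: StructureFrame, site: TitratableSite) -> np.ndarray:
    names = set(site.charge_sets["protonated"]) | set(site.charge_sets["deprotonated"])
    pts = [
        a.position
        for a in frame.residue_atoms(site.chain_id, site.residue_id)
        if a.atom_name in names
    ]
    if not pts:
        raise ValueError(f"site {site.site_id}: functional atoms missing from frame")
    return np.mean(pts, axis=0)


def transfer_free_energy(
    frame: StructureFrame,
    site: TitratableSite,
    state: str,
    sites: Sequence[TitratableSite],
    assignment: ProtonationAssignment,
    environment: FrameEnvironment,
    constants: PhysicalConstants,
    settings: SolverSettings | None = None,
) -> tuple[float, float]:
    """(ΔG_protein, ΔG_water) for the site held in ``state``.

    The protein leg carries the whole frame with every titratable site's
    charges fixed by ``assignment`` (the site of interest overridden to
    ``state``), the membrane dielectric, and the selected explicit ions.
    The water leg carries the excised model compound with the same grid
    spacings, cavity permittivity and solvent, but no membrane/ions and
    no background charges.
    """
    settings = settings or SolverSettings()
    center = _site_center(frame, site)
    fine_grid = _site_fine_grid(center, settings)

    forced = assignment.copy()
    forced.states[site.site_id] = state
    protein_frame = apply_assignment(frame, sites, forced)
    g_protein = _leg_energy(
        protein_frame,
        environment.membrane,
        environment.ions.positions,
        environment.ions.charges,
        fine_grid,
        constants,
        settings,
        settings.region_values,
    )

    model = _model_compound_frame(frame, site).with_charges(site.charge_map(state))
    g_water = _leg_energy(
        model,
        None,
        np.zeros((0, 3)),
        np.zeros(0),
        fine_grid,
        constants,
        settings,
        settings.region_values,
    )
    return g_protein, g_water


def site_pka(
    frame: StructureFrame,
    site: TitratableSite,
    sites: Sequence[TitratableSite],
    assignment: ProtonationAssignment,
    environment: FrameEnvironment,
    constants: PhysicalConstants,
    settings: SolverSettings | None = None,
) -> float:
    """Single-frame pKa of one site from the four-leg thermodynamic cycle."""
    gp_prot, gw_prot = transfer_free_energy(
        frame, site, "protonated", sites, assignment, environment, constants, settings
    )
    gp_deprot, gw_deprot = transfer_free_energy(
        frame, site, "deprotonated", sites, assignment, environment, constants, settings
    )
    ddg = (gp_deprot - gp_prot) - (gw_deprot - gw_prot)
    return site.reference_pka + ddg / constants.ln10_kbt


def equivalent_subunit_sites(
    sites: Sequence[TitratableSite], site: TitratableSite
) -> list[TitratableSite]:
    """Sites in other chains with the same residue name and number."""
    return [
        s
        for s in sites
        if s.residue_name == site.residue_name and s.residue_id == site.residue_id
    ]


def ensemble_pka(
    ensemble: FrameEnsemble,
    site: TitratableSite,
    sites: Sequence[TitratableSite],
    assignment: ProtonationAssignment,
    constants: PhysicalConstants,
    settings: SolverSettings | None = None,
    equivalent_sites: Sequence[TitratableSite] | None = None,
    environments: Sequence[FrameEnvironment] | None = None,
) -> PKaEstimate:
    """Mean ± SD pKa over every (frame, equivalent subunit site) sample.

    Failed samples are dropped with a warning and reduce n.
    """
    if equivalent_sites is None:
        equivalent_sites = equivalent_subunit_sites(sites, site)
    if environments is None:
        environments = [build_environment(f) for f in ensemble.frames]
    samples: list[float] = []
    for frame, env in zip(ensemble.frames, environments):
        for sub_site in equivalent_sites:
            try:
                samples.append(
                    site_pka(frame, sub_site, sites, assignment, env, constants, settings)
                )
            except (SolverError, ValueError) as exc:
                logger.warning(
                    "pKa sample failed for %s in frame %s: %s",
                    sub_site.site_id,
                    frame.frame_label,
                    exc,
                )
    if not samples:
        raise SolverError(f"no pKa sample succeeded for site {site.site_id}")
    arr = np.array(samples)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return PKaEstimate(
        site_id=site.site_id,
        residue_name=site.residue_name,
        mean_pka=float(arr.mean()),
        sd=sd,
        n=len(arr),
        samples=[float(s) for s in samples],
    )


def compute_state_pka_table(
    ensemble: FrameEnsemble,
    sites: Sequence[TitratableSite],
    assignment: ProtonationAssignment,
    constants: PhysicalConstants,
    settings: SolverSettings | None = None,
    round_index: int = 0,
    average_subunits: bool = True,
) -> StatePKaTable:
    """Ensemble pKa table for every unique residue position.

    With ``average_subunits`` (default) chains are treated as equivalent
    subunits: one estimate per (residue name, residue id), averaged over
    all chains, reported under the first chain's site id.
    """
    environments = [build_environment(f) for f in ensemble.frames]
    groups: dict[tuple[str, int], list[TitratableSite]] = {}
    for s in sites:
        key = (s.residue_name, s.residue_id) if average_subunits else (
            s.residue_name,
            s.residue_id,
        ) + (s.chain_id,)
        groups.setdefault(key, []).append(s)

    estimates: dict[str, PKaEstimate] = {}
    for key in sorted(groups):
        members = groups[key]
        rep = members[0]
        est = ensemble_pka(
            ensemble,
            rep,
            sites,
            assignment,
            constants,
            settings,
            equivalent_sites=members,
            environments=environments,
        )
        estimates[rep.site_id] = est
    return StatePKaTable(state=ensemble.state_label, estimates=estimates, round_index=round_index)
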