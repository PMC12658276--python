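"""Finite-difference linearized Poisson-Boltzmann solver.

Solves, on a regular cubic grid,

    div(eps(r) grad phi(r)) - kappa_bar_sq(r) * phi(r) = -4*pi*k_c*rho(r)

where phi is in kcal/(mol·e), eps is the relative permittivity, rho the
fixed-charge density (e/Å³), k_c the Coulomb constant and kappa_bar_sq the
modified Debye screening coefficient Σ_i z_i² e² c∞,i / (k_B T) carried by
:class:`~membpka.constants.PhysicalConstants` (it vanishes inside the
protein and the membrane, where mobile ions cannot go).

Discretization: 7-point stencil with harmonic-mean face permittivities;
Dirichlet boundary values from the sum of Debye-Hückel monopole potentials
of all source charges; preconditioned conjugate-gradient solve.  Point
charges are spread to the eight surrounding grid nodes (trilinear), whose
spurious grid self-energy cancels in the thermodynamic-cycle differences
as long as both cycle legs use the same grid.

Two-pass "focusing" (coarse solve supplying boundary values for a finer
grid centered on the site of interest, default spacings 1.5 -> 0.5 Å) is
provided by :func:`focused_solve`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constants import PhysicalConstants
from .environment_model import MembraneGeometry
from .errors import SolverError
from .structure_io import StructureFrame

DEFAULT_REGION_VALUES: dict[str, float] = {
    "reference": 1.0,
    "membrane_core": 4.0,
    "headgroups": 8.0,
    "protein": 8.0,
    "solvent": 80.0,
}

# region codes in DielectricMap.region
REGION_SOLVENT = 0
REGION_PROTEIN = 1
REGION_CORE = 2
REGION_HEADGROUP = 3


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned regular grid: origin (Å), spacing (Å), dims (nodes)."""

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(d < 2 for d in self.dims):
            raise ValueError("grid must have at least 2 nodes per axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.dims)

    @property
    def upper(self) -> np.ndarray:
        return self.origin + self.spacing * (np.array(self.dims) - 1)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[i] + self.spacing * np.arange(self.dims[i]) for i in range(3)
        )

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        pts = np.atleast_2d(points)
        lo = self.origin + margin
        hi = self.upper - margin
        return np.all((pts >= lo) & (pts <= hi), axis=1)

    def node_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ax = self.axes()
        return np.meshgrid(*ax, indexing="ij")


@dataclass
class DielectricMap:
    grid: GridSpec
    epsilon: np.ndarray
    region: np.ndarray
    region_values: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_REGION_VALUES))


@dataclass
class ScreeningMap:
    grid: GridSpec
    kappa_sq: np.ndarray


@dataclass
class PotentialGrid:
    grid: GridSpec
    phi: np.ndarray
    iterations: int = 0
    residual: float = 0.0

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of phi at arbitrary points inside the grid."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if not np.all(self.grid.contains(pts)):
            raise ValueError("interpolation point outside the grid")
        f = (pts - self.grid.origin) / self.grid.spacing
        i0 = np.clip(np.floor(f).astype(int), 0, np.array(self.grid.dims) - 2)
        t = f - i0
        out = np.zeros(len(pts))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (
                        (t[:, 0] if dx else 1 - t[:, 0])
                        * (t[:, 1] if dy else 1 - t[:, 1])
                        * (t[:, 2] if dz else 1 - t[:, 2])
                    )
                    out += w * self.phi[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
        return out


# ---------------------------------------------------------------------------
# grid construction


def build_grid(frame_or_points, spacing: float, padding: float) -> GridSpec:
    """Cubic-cell grid covering the atom bounding box plus padding.

    ``dims = ceil(extent / spacing) + 1`` per axis, so the nominal upper
    corner is always inside the node lattice.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if padding < 0:
        raise ValueError("padding must be non-negative")
    if isinstance(frame_or_points, StructureFrame):
        pts = frame_or_points.positions
    else:
        pts = np.atleast_2d(np.asarray(frame_or_points, dtype=float))
    if pts.size == 0:
        raise ValueError("cannot build a grid around zero atoms")
    lo = pts.min(axis=0) - padding
    hi = pts.max(axis=0) + padding
    extent = hi - lo
    dims = tuple(int(math.ceil(e / spacing - 1e-9)) + 1 for e in extent)
    return GridSpec(origin=lo, spacing=spacing, dims=dims)


def build_dielectric_map(
    frame: StructureFrame,
    grid: GridSpec,
    membrane: MembraneGeometry | None = None,
    region_values: Mapping[str, float] | None = None,
) -> DielectricMap:
    """Voxel permittivities: protein sphere-union over membrane slab over solvent.

    The protein region is the union of atom spheres at their input radii
    (no solvent-probe surface, no Stern layer); only non-ion, non-lipid
    heavy atoms carve cavities.
    """
    rv = dict(DEFAULT_REGION_VALUES)
    if region_values:
        rv.update(region_values)
    for key in ("protein", "solvent", "membrane_core", "headgroups"):
        if key not in rv:
            raise ValueError(f"region_values missing {key!r}")

    region = np.full(grid.shape, REGION_SOLVENT, dtype=np.uint8)
    if membrane is not None:
        zax = grid.axes()[2]
        zregion = membrane.region_of_z(zax)  # 0 solvent / 1 headgroup / 2 core
        region[:, :, zregion == 1] = REGION_HEADGROUP
        region[:, :, zregion == 2] = REGION_CORE

    ax, ay, az = grid.axes()
    h = grid.spacing
    for atom in frame.protein_atoms(include_hydrogens=False):
        r = atom.radius
        if r <= 0:
            continue
        cx, cy, cz = atom.position
        ix = np.searchsorted(ax, (cx - r, cx + r))
        iy = np.searchsorted(ay, (cy - r, cy + r))
        iz = np.searchsorted(az, (cz - r, cz + r))
        sl = (slice(max(ix[0] - 1, 0), ix[1] + 1),
              slice(max(iy[0] - 1, 0), iy[1] + 1),
              slice(max(iz[0] - 1, 0), iz[1] + 1))
        X, Y, Z = np.meshgrid(ax[sl[0]], ay[sl[1]], az[sl[2]], indexing="ij")
        inside = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= r * r
        region[sl][inside] = REGION_PROTEIN

    eps = np.empty(grid.shape, dtype=float)
    eps[region == REGION_SOLVENT] = rv["solvent"]
    eps[region == REGION_PROTEIN] = rv["protein"]
    eps[region == REGION_CORE] = rv["membrane_core"]
    eps[region == REGION_HEADGROUP] = rv["headgroups"]
    return DielectricMap(grid=grid, epsilon=eps, region=region, region_values=rv)


def build_screening_map(dielectric: DielectricMap, constants: PhysicalConstants) -> ScreeningMap:
    """kappa_bar_sq per voxel: bulk value in solvent, zero elsewhere."""
    kappa_sq = np.zeros(dielectric.grid.shape)
    kappa_sq[dielectric.region == REGION_SOLVENT] = constants.kappa_bar_sq()
    return ScreeningMap(grid=dielectric.grid, kappa_sq=kappa_sq)


def spread_charges(grid: GridSpec, positions: np.ndarray, charges: np.ndarray) -> np.ndarray:
    """Trilinear assignment of point charges to the eight surrounding nodes."""
    pts = np.atleast_2d(np.asarray(positions, dtype=float))
    q = np.asarray(charges, dtype=float).ravel()
    if len(pts) != len(q):
        raise ValueError("positions and charges length mismatch")
    if len(pts) and not np.all(grid.contains(pts)):
        raise ValueError("charge position outside the grid")
    out = np.zeros(grid.shape)
    if len(pts) == 0:
        return out
    f = (pts - grid.origin) / grid.spacing
    i0 = np.clip(np.floor(f).astype(int), 0, np.array(grid.dims) - 2)
    t = f - i0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (t[:, 0] if dx else 1 - t[:, 0])
                    * (t[:, 1] if dy else 1 - t[:, 1])
                    * (t[:, 2] if dz else 1 - t[:, 2])
                )
                np.add.at(out, (i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz), w * q)
    return out


# ---------------------------------------------------------------------------
# boundary condition


def debye_huckel_boundary(
    grid: GridSpec,
    positions: np.ndarray,
    charges: np.ndarray,
    constants: PhysicalConstants,
    eps_solvent: float,
) -> np.ndarray:
    """phi on the full grid array with only boundary faces filled in.

    Each source charge contributes a screened monopole
    k_c*q*exp(-kappa*r)/(eps_s*r) at every boundary node.
    """
    phi = np.zeros(grid.shape)
    if len(np.atleast_2d(positions)) == 0:
        return phi
    kappa = constants.debye_kappa(eps_solvent)
    X, Y, Z = grid.node_coordinates()
    mask = np.zeros(grid.shape, dtype=bool)
    mask[0, :, :] = mask[-1, :, :] = True
    mask[:, 0, :] = mask[:, -1, :] = True
    mask[:, :, 0] = mask[:, :, -1] = True
    bx, by, bz = X[mask], Y[mask], Z[mask]
    vals = np.zeros(bx.shape)
    for pos, q in zip(np.atleast_2d(positions), np.ravel(charges)):
        r = np.sqrt((bx - pos[0]) ** 2 + (by - pos[1]) ** 2 + (bz - pos[2]) ** 2)
        r = np.maximum(r, 1e-6)
        vals += constants.coulomb_constant * q * np.exp(-kappa * r) / (eps_solvent * r)
    phi[mask] = vals
    return phi


# ---------------------------------------------------------------------------
# the solve


def _harmonic_faces(eps: np.ndarray, axis: int) -> np.ndarray:
    a = eps
    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_lo[axis] = slice(0, -1)
    sl_hi[axis] = slice(1, None)
    e1, e2 = a[tuple(sl_lo)], a[tuple(sl_hi)]
    return 2.0 * e1 * e2 / (e1 + e2)


def solve_linearized_pb(
    positions: np.ndarray,
    charges: np.ndarray,
    dielectric: DielectricMap,
    screening: ScreeningMap,
    constants: PhysicalConstants,
    boundary: np.ndarray | None = None,
    tol: float = 1e-6,
    maxiter: int = 10000,
) -> PotentialGrid:
    """Solve the discrete linearized PB equation for the given point charges.

    ``boundary`` optionally supplies Dirichlet values on the outer faces
    (full-shape array, interior ignored); by default the Debye-Hückel
    monopole sum of the charges is used.  Raises :class:`SolverError` if
    the conjugate-gradient iteration does not reach the relative residual
    tolerance within ``maxiter`` iterations.
    """
    grid = dielectric.grid
    if screening.grid.shape != grid.shape:
        raise ValueError("dielectric and screening maps must share one grid")
    h = grid.spacing
    nx, ny, nz = grid.shape

    rho_grid = spread_charges(grid, positions, charges)  # total charge per node, e
    source = 4.0 * math.pi * constants.coulomb_constant * rho_grid / h**3

    if boundary is None:
        eps_solvent = float(dielectric.region_values["solvent"])
        boundary = debye_huckel_boundary(grid, positions, charges, constants, eps_solvent)

    # face permittivities
    fx = _harmonic_faces(dielectric.epsilon, 0)
    fy = _harmonic_faces(dielectric.epsilon, 1)
    fz = _harmonic_faces(dielectric.epsilon, 2)

    interior = np.zeros(grid.shape, dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True
    n_int = int(interior.sum())
    if n_int == 0:
        raise ValueError("grid has no interior nodes")
    idx = -np.ones(grid.shape, dtype=np.int64)
    idx[interior] = np.arange(n_int)

    inv_h2 = 1.0 / h**2
    diag = np.zeros(grid.shape)
    b = source.copy()

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    faces = (
        (fx, (1, 0, 0)),
        (fy, (0, 1, 0)),
        (fz, (0, 0, 1)),
    )
    for f, (dx, dy, dz) in faces:
        # face between node p=(i,j,k) and n=(i+dx, j+dy, k+dz)
        p_sl = (slice(0, nx - dx or None), slice(0, ny - dy or None), slice(0, nz - dz or None))
        n_sl = (slice(dx, None), slice(dy, None), slice(dz, None))
        coeff = f * inv_h2
        p_int = interior[p_sl]
        n_int_mask = interior[n_sl]

        # accumulate diagonal for both sides of the face
        diag[p_sl] += coeff
        diag[n_sl] += coeff

        both = p_int & n_int_mask
        rows.append(idx[p_sl][both])
        cols.append(idx[n_sl][both])
        vals.append(-coeff[both])
        rows.append(idx[n_sl][both])
        cols.append(idx[p_sl][both])
        vals.append(-coeff[both])

        # neighbor on boundary: move its Dirichlet value to the rhs
        pb = p_int & ~n_int_mask
        if pb.any():
            np.add.at(
                b[p_sl], np.nonzero(pb), coeff[pb] * boundary[n_sl][pb]
            )
        nb = n_int_mask & ~p_int
        if nb.any():
            np.add.at(
                b[n_sl], np.nonzero(nb), coeff[nb] * boundary[p_sl][nb]
            )

    diag_int = diag[interior] + screening.kappa_sq[interior]
    rows.append(np.arange(n_int))
    cols.append(np.arange(n_int))
    vals.append(diag_int)

    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_int, n_int),
    )
    rhs = b[interior]

    M = sp.diags(1.0 / diag_int)
    x, info = spla.cg(A, rhs, rtol=tol, maxiter=maxiter, M=M)
    res = float(np.linalg.norm(A @ x - rhs) / max(np.linalg.norm(rhs), 1e-300))
    if info != 0:
        raise SolverError(
            f"PB solve did not converge in {maxiter} iterations (relative residual {res:.2e})"
        )

    phi = boundary.copy()
    phi[interior] = x
    return PotentialGrid(grid=grid, phi=phi, iterations=maxiter if info else 0, residual=res)


def focused_solve(
    positions: np.ndarray,
    charges: np.ndarray,
    frame: StructureFrame,
    membrane: MembraneGeometry | None,
    constants: PhysicalConstants,
    coarse_spacing: float = 1.5,
    fine_spacing: float = 0.5,
    padding: float = 10.0,
    focus_center: np.ndarray | None = None,
    focus_half_extent: float = 8.0,
    region_values: Mapping[str, float] | None = None,
    fine_grid: GridSpec | None = None,
    tol: float = 1e-6,
    maxiter: int = 10000,
) -> tuple[PotentialGrid, PotentialGrid]:
    """Two-pass solve: coarse grid over the whole frame, fine grid focused
    on ``focus_center`` with boundary values interpolated from the coarse
    potential.  Returns (fine, coarse) potentials.

    An explicit ``fine_grid`` pins the fine lattice exactly; thermodynamic
    cycles must reuse one fine grid across their legs so that the grid
    self-energy of the spread charges cancels in the double difference.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    charges = np.asarray(charges, dtype=float).ravel()
    coarse_grid = build_grid(frame, coarse_spacing, padding)
    coarse_eps = build_dielectric_map(frame, coarse_grid, membrane, region_values)
    coarse_kap = build_screening_map(coarse_eps, constants)
    coarse = solve_linearized_pb(
        positions, charges, coarse_eps, coarse_kap, constants, tol=tol, maxiter=maxiter
    )

    if fine_grid is None:
        if focus_center is None:
            focus_center = positions.mean(axis=0) if len(positions) else coarse_grid.origin
        focus_center = np.asarray(focus_center, dtype=float)
        lo = np.maximum(focus_center - focus_half_extent, coarse_grid.origin)
        hi = np.minimum(focus_center + focus_half_extent, coarse_grid.upper)
        if np.allclose(coarse_spacing, fine_spacing) and np.all(lo <= coarse_grid.origin + 1e-9) \
                and np.all(hi >= coarse_grid.upper - 1e-9):
            return coarse, coarse
        extent = hi - lo
        dims = tuple(int(math.ceil(e / fine_spacing - 1e-9)) + 1 for e in extent)
        fine_grid = GridSpec(origin=lo, spacing=fine_spacing, dims=dims)
    else:
        if np.any(fine_grid.origin < coarse_grid.origin - 1e-9) or np.any(
            fine_grid.upper > coarse_grid.upper + 1e-9
        ):
            raise ValueError("fine grid extends beyond the coarse grid")
    fine_eps = build_dielectric_map(frame, fine_grid, membrane, region_values)
    fine_kap = build_screening_map(fine_eps, constants)

    inside = fine_grid.contains(positions) if len(positions) else np.zeros(0, dtype=bool)
    boundary = np.zeros(fine_grid.shape)
    mask = np.zeros(fine_grid.shape, dtype=bool)
    mask[0, :, :] = mask[-1, :, :] = True
    mask[:, 0, :] = mask[:, -1, :] = True
    mask[:, :, 0] = mask[:, :, -1] = True
    X, Y, Z = fine_grid.node_coordinates()
    bpts = np.column_stack([X[mask], Y[mask], Z[mask]])
    boundary[mask] = coarse.interpolate(bpts)

    fine = solve_linearized_pb(
        positions[inside],
        charges[inside],
        fine_eps,
        fine_kap,
        constants,
        boundary=boundary,
        tol=tol,
        maxiter=maxiter,
    )
    return fine, coarse


# ---------------------------------------------------------------------------
# energies


def electrostatic_free_energy(
    phi: PotentialGrid, positions: np.ndarray, charges: np.ndarray
) -> float:
    """Charging free energy ΔG = ½ Σ q_i φ(r_i) in kcal/mol.

    φ must have been solved for exactly these charges; grid self-energies
    are meant to cancel between thermodynamic-cycle legs computed on the
    same grid and spacing.
    """
    q = np.asarray(charges, dtype=float).ravel()
    if q.size == 0:
        return 0.0
    vals = phi.interpolate(positions)
    return float(0.5 * np.sum(q * vals))


def coulomb_energy(
    z1: float, z2: float, r: float, eps_r: float, constants: PhysicalConstants | None = None
) -> float:
    """Coulomb interaction k_c·z1·z2/(eps_r·r) in kcal/mol (r in Å)."""
    if r <= 0:
        raise ValueError("distance must be positive")
    if eps_r <= 0:
        raise ValueError("relative permittivity must be positive")
    kc = (constants or PhysicalConstants()).coulomb_constant
    return kc * z1 * z2 / (eps_r * r)


# ---------------------------------------------------------------------------
# linearization error analysis


@dataclass
class LinearizationReport:
    """Error budget of truncating exp(x) at successive Taylor orders."""

    x: float
    exact: float
    table: pd.DataFrame

    def order(self, k: int) -> pd.Series:
        return self.table.loc[self.table["order"] == k].iloc[0]


def linearization_error_report(
    delta_e: float, kbt: float, max_order: int = 3
) -> LinearizationReport:
    """Quantify the error of the linearized Boltzmann factor.

    For an interaction energy ΔE the Boltzmann factor is exp(x) with
    x = |ΔE|/kBT.  The report compares exp(x) with its Taylor partial
    sums Σ_{j<=k} x^j/j! for k = 1..max_order, giving the relative error
    and the equivalent error in pKa units, log10(exact/approx).
    """
    if kbt <= 0:
        raise ValueError("kBT must be positive")
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    x = abs(delta_e) / kbt
    exact = math.exp(x)
    rows = []
    partial = 1.0
    term = 1.0
    for k in range(1, max_order + 1):
        term *= x / k
        partial += term
        rel = (exact - partial) / exact
        pka = math.log(exact / partial) / math.log(10.0) if partial > 0 else math.nan
        rows.append(
            {
                "order": k,
                "approximation": partial,
                "relative_error": rel,
                "pka_error": pka,
            }
        )
    return LinearizationReport(x=x, exact=exact, table=pd.DataFrame(rows))
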