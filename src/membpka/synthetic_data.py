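"""Synthetic inputs: toy membrane systems, jittered ensembles, dose-response
curves, mutant panels, and the exhaustive microstate titration oracle.

Everything the pipeline consumes can be generated here without any
download: membrane-embedded toy charge systems stand in for MD frames
(titratable side-chain fragments, background charges, pseudo-lipid marker
atoms realizing a slab, explicit ions), Gaussian-jittered copies of one
frame stand in for trajectory snapshots, and Hill-equation curves with
Gaussian noise stand in for two-electrode voltage-clamp recordings.

The microstate oracle is the independent ground truth for the whole
electrostatics stack: for up to three interacting sites it enumerates
all protonation microstates, Boltzmann-averages the per-site protonation
against pH, and reports exact apparent pKa½ values.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import PhysicalConstants
from .errors import ToySpecError
from .functional_analysis import DoseResponseCurve, PropertyScale
from .structure_io import (
    DEFAULT_CHARGE_SETS,
    DEFAULT_FORM,
    REFERENCE_PKAS,
    AtomRecord,
    FrameEnsemble,
    StructureFrame,
)

# functional atom of each titratable residue class (matches the charge sets)
_FUNCTIONAL_ATOM = {"ASP": "CG", "GLU": "CD", "HIS": "NE2", "LYS": "NZ"}


@dataclass
class ToySystemSpec:
    """Recipe for a deterministic membrane-embedded toy frame.

    ``sites`` is a sequence of (residue_name, position-of-functional-atom);
    ``background_charges`` of (position, charge); ``ions`` of
    (species, position).  The membrane, if present, is a slab of marker
    atoms: phosphorus on both leaflets, terminal methyls at the midplane.
    """

    sites: Sequence[tuple[str, Sequence[float]]] = ()
    background_charges: Sequence[tuple[Sequence[float], float]] = ()
    ions: Sequence[tuple[str, Sequence[float]]] = ()
    membrane: Mapping[str, float] | None = None  # keys: thickness, midplane_z, half_width
    jitter_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for resname, _ in self.sites:
            if resname.upper() not in REFERENCE_PKAS:
                raise ToySpecError(f"{resname} is not a titratable residue type")


def make_toy_membrane_system(spec: ToySystemSpec) -> StructureFrame:
    """Build the frame described by the spec (deterministic).

    Each titratable site becomes a two-atom side-chain fragment: a neutral
    C-beta and the functional atom carrying the residue's default-form
    charge.  Lipid markers are charge-free so membrane geometry stays
    decoupled from electrostatics.  Raises :class:`ToySpecError` when two
    atoms land closer than 0.5 Å.
    """
    atoms: list[AtomRecord] = []
    resid = 0
    for resname, pos in spec.sites:
        resid += 1
        resname = resname.upper()
        pos = np.asarray(pos, dtype=float)
        fatom = _FUNCTIONAL_ATOM[resname]
        default_q = DEFAULT_CHARGE_SETS[resname][DEFAULT_FORM[resname]]
        atoms.append(
            AtomRecord("CB", "C", resname, resid, "A", pos + np.array([0.0, 0.0, 1.5]),
                       0.0, 1.7)
        )
        atoms.append(
            AtomRecord(fatom, "N" if fatom in ("NZ", "NE2") else "C", resname, resid, "A",
                       pos, float(default_q.get(fatom, 0.0)), 1.5)
        )
        # His spreads the proton over two ring nitrogens
        if resname == "HIS":
            atoms.append(
                AtomRecord("ND1", "N", resname, resid, "A", pos + np.array([1.3, 0.0, 0.0]),
                           0.0, 1.5)
            )

    for i, (pos, q) in enumerate(spec.background_charges, start=1):
        atoms.append(
            AtomRecord("Q", "C", "DUM", 1000 + i, "A", np.asarray(pos, dtype=float),
                       float(q), 1.5)
        )

    for i, (species, pos) in enumerate(spec.ions, start=1):
        species = species.upper()
        from .structure_io import ION_VALENCE

        if species not in ION_VALENCE:
            raise ToySpecError(f"unknown ion species {species!r}")
        atoms.append(
            AtomRecord(species, species, species, 2000 + i, "I",
                       np.asarray(pos, dtype=float), ION_VALENCE[species], 1.4)
        )

    if spec.membrane is not None:
        thickness = float(spec.membrane["thickness"])
        midplane = float(spec.membrane.get("midplane_z", 0.0))
        half_width = float(spec.membrane.get("half_width", 15.0))
        n_side = int(spec.membrane.get("n_per_side", 4))
        xs = np.linspace(-half_width, half_width, n_side)
        lip = 0
        for x in xs:
            for y in xs:
                lip += 1
                for zsign, tag in ((+1, "U"), (-1, "L")):
                    atoms.append(
                        AtomRecord("P", "P", "LIP", 3000 + lip * 2 + (zsign < 0), tag,
                                   np.array([x, y, midplane + zsign * thickness / 2.0]),
                                   0.0, 0.0)
                    )
        # terminal methyls define the midplane
        for j, x in enumerate(xs, start=1):
            atoms.append(
                AtomRecord("C216", "C", "LIP", 4000 + j, "M",
                           np.array([x, 0.0, midplane]), 0.0, 0.0)
            )

    frame = StructureFrame(atoms=atoms, frame_label="toy")
    pos = frame.positions
    if len(pos) > 1:
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 0.5:
            i, j = np.unravel_index(np.argmin(d), d.shape)
            raise ToySpecError(
                f"atoms {frame.atoms[i].key} and {frame.atoms[j].key} overlap "
                f"({d.min():.2f} Å < 0.5 Å)"
            )
    return frame


def jitter_frames(
    frame: StructureFrame,
    n_frames: int = 5,
    amplitude: float = 0.25,
    seed: int | None = None,
    state_label: str = "closed",
    labels: Sequence[str] | None = None,
) -> FrameEnsemble:
    """Ensemble of Gaussian-jittered copies emulating trajectory snapshots.

    Frame 0 is the unperturbed input; later frames displace every atom
    coordinate by zero-mean Gaussian noise of the given amplitude (Å).
    Default labels mimic snapshot times 0, 2, 4, 6, 8 ns.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [str(2 * i) for i in range(n_frames)]
    frames = []
    from dataclasses import replace

    for i in range(n_frames):
        if i == 0 or amplitude == 0:
            disp = np.zeros((len(frame), 3))
        else:
            disp = rng.normal(0.0, amplitude, size=(len(frame), 3))
        atoms = [
            replace(a, position=a.position + d) for a, d in zip(frame.atoms, disp)
        ]
        frames.append(StructureFrame(atoms=atoms, frame_label=str(labels[i])))
    return FrameEnsemble(frames=frames, state_label=state_label)


# ---------------------------------------------------------------------------
# dose-response and mutant panels


def hill_response(ph, ph50: float, n_h: float, i_max: float, transition: str = "activation"):
    """I = I_max / [1 + (10^-pH50 / 10^-pH)^nH]; mirrored midpoint for SSD.

    Activation: response rises as pH falls below pH50.  SSD availability
    falls as the conditioning pH falls below pHD50.
    """
    ph = np.asarray(ph, dtype=float)
    if transition == "activation":
        return i_max / (1.0 + 10.0 ** (n_h * (ph - ph50)))
    return i_max / (1.0 + 10.0 ** (n_h * (ph50 - ph)))


def simulate_dose_response(
    ph50: float,
    n_h: float,
    i_max: float,
    ph_grid: Sequence[float],
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int | None = None,
    transition: str = "activation",
) -> DoseResponseCurve:
    """Hill-equation responses with i.i.d. Gaussian noise, replicate-averaged."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    ph = np.asarray(ph_grid, dtype=float)
    clean = hill_response(ph, ph50, n_h, i_max, transition)
    reps = clean[None, :] + rng.normal(0.0, noise_sd, size=(n_replicates, ph.size))
    mean = reps.mean(axis=0)
    sem = reps.std(axis=0, ddof=1) / math.sqrt(n_replicates) if n_replicates > 1 else None
    return DoseResponseCurve(ph=ph, response=mean, sem=sem, transition=transition, n=n_replicates)


def simulate_mutant_panel(
    position: int,
    substitutions: Sequence[str],
    scale: "PropertyScale",
    slope: float,
    intercept: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
    response: str = "ph50",
) -> pd.DataFrame:
    """Mutant panel with response = intercept + slope·scale(aa) + noise."""
    if len(substitutions) < 4:
        raise ValueError("a panel needs at least 4 substitutions")
    rng = np.random.default_rng(seed)
    rows = []
    for aa in substitutions:
        if aa not in scale.values:
            raise KeyError(f"substitution {aa!r} absent from scale {scale.name!r}")
        val = intercept + slope * scale.values[aa] + rng.normal(0.0, noise_sd)
        rows.append({"position": position, "substitution": aa, response: val})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# microstate oracle


@dataclass
class MicrostateTitration:
    """Exact per-site titration of a small interacting system."""

    site_names: list[str]
    ph_grid: np.ndarray
    curves: np.ndarray  # (n_sites, n_ph) mean protonation
    pka_half: np.ndarray  # apparent pKa½ per site


def microstate_titration_oracle(
    residue_names: Sequence[str],
    distances: np.ndarray,
    eps_r: float,
    constants: PhysicalConstants,
    ph_grid: Sequence[float] | None = None,
    reference_pkas: Mapping[str, float] | None = None,
) -> MicrostateTitration:
    """Brute-force titration of ≤3 coupled sites.

    Microstate energy (x_i = 1 when site i holds its proton):

        E(x)/kBT = Σ_i ln10·(pH − pKa_ref,i)·x_i
                 + Σ_{i<j} k_c·q_i(x_i)·q_j(x_j)/(eps_r·r_ij·kBT)

    with q = x − 1 for acids (Asp/Glu) and q = x for bases (His/Lys).
    Boltzmann averaging gives exact per-site protonation curves; pKa½ is
    the pH at half protonation, located by monotone interpolation.
    """
    names = [r.upper() for r in residue_names]
    if len(names) > 3:
        raise ValueError("oracle limited to 3 sites (8 microstates)")
    refs = dict(REFERENCE_PKAS)
    if reference_pkas:
        refs.update({k.upper(): v for k, v in reference_pkas.items()})
    for n in names:
        if n not in refs:
            raise ValueError(f"{n} has no reference pKa")
    dist = np.atleast_2d(np.asarray(distances, dtype=float))
    n_sites = len(names)
    if dist.shape != (n_sites, n_sites):
        raise ValueError("distance matrix shape mismatch")
    if ph_grid is None:
        ph_grid = np.arange(-2.0, 16.001, 0.01)
    ph_grid = np.asarray(ph_grid, dtype=float)

    kbt = constants.kbt
    ln10 = math.log(10.0)
    acids = [n in {"ASP", "GLU"} for n in names]

    states = list(itertools.product((0, 1), repeat=n_sites))
    pair_e = np.zeros(len(states))
    for si, x in enumerate(states):
        q = [xi - 1 if acid else xi for xi, acid in zip(x, acids)]
        e = 0.0
        for i in range(n_sites):
            for j in range(i + 1, n_sites):
                if q[i] and q[j]:
                    e += constants.coulomb_constant * q[i] * q[j] / (eps_r * dist[i, j])
        pair_e[si] = e / kbt

    nx = np.array([sum(x) for x in states])
    site_x = np.array(states, dtype=float)  # (n_states, n_sites)
    ref_term = np.array([
        sum(ln10 * (-refs[names[i]]) * x[i] for i in range(n_sites)) for x in states
    ])
    # E/kBT at pH: ln10*pH*nx + ref_term + pair_e
    curves = np.zeros((n_sites, ph_grid.size))
    for k, ph in enumerate(ph_grid):
        e = ln10 * ph * nx + ref_term + pair_e
        w = np.exp(-(e - e.min()))
        w /= w.sum()
        curves[:, k] = site_x.T @ w

    pka_half = np.full(n_sites, np.nan)
    for i in range(n_sites):
        c = curves[i]
        # protonation decreases with pH; find the 0.5 crossing
        above = c >= 0.5
        if above.any() and (~above).any():
            k = int(np.nonzero(above)[0][-1])
            if k + 1 < c.size:
                c0, c1 = c[k], c[k + 1]
                pka_half[i] = ph_grid[k] + (c0 - 0.5) / (c0 - c1) * (
                    ph_grid[k + 1] - ph_grid[k]
                )
    return MicrostateTitration(
        site_names=names, ph_grid=ph_grid, curves=curves, pka_half=pka_half
    )

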