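# Methods

## Model overview

`membpka` computes per-residue pKas of membrane proteins from structure
ensembles via continuum electrostatics, then derives pH-sensor
predictions and analyses functional pH-dependence data. The chain is:

1. per-frame environment: membrane slab geometry and explicit-ion
   selection;
2. linearized Poisson–Boltzmann (PB) solves on focused grids;
3. a thermodynamic cycle converting electrostatic work into a pKa
   shift from the water reference value;
4. ensemble averaging over frames and equivalent subunits;
5. a round-based protonation-update protocol to self-consistency;
6. sensor ranking, Henderson–Hasselbalch protonation fractions, and
   driver/stabilizer classification;
7. Hill fits, effect classes, mutant-cycle additivity and side-chain
   property regressions for electrophysiology panels.

## Units and constants

Lengths in Å, energies in kcal/mol, charges in elementary charges,
potentials in kcal/(mol·e). Coulomb constant k_c = 332.06
kcal·Å/(mol·e²); k_B = 0.0019872 kcal/(mol·K). The default temperature
is 310 K (k_BT = 0.616 kcal/mol, thermal voltage ≈ 27 mV) and the
default ionic strength 0.15 M — both explicit configuration, never
hard-coded into formulas. The worked linearization example is evaluated
at the ambient-temperature k_BT = 0.593 kcal/mol and ε_r = 78, the only
values consistent with its printed numbers (exact factor 4.207, Taylor
orders 2.437/3.469/3.964, −0.852 kcal/mol at 5 Å); the discrepancy with
the 310 K simulation temperature is inherited from the source material
and deliberately not reconciled.

## The PB solver

The linearized equation ∇·(ε∇φ) − κ̄²φ = −4π k_c ρ is discretized with
a 7-point stencil on a regular cubic grid; face permittivities are the
harmonic means of the adjacent voxel values. The screening coefficient
κ̄² = 4π k_c Σᵢ zᵢ²c∞,ᵢ/(k_BT) is non-zero only in solvent voxels (the
membrane and the protein interior exclude mobile ions). Dirichlet
boundary values are the sum of Debye–Hückel monopole potentials of all
source charges. Point charges are spread trilinearly onto the eight
surrounding nodes. The symmetric positive-definite system is solved by
Jacobi-preconditioned conjugate gradients to a relative residual of
1e-6 (default cap 10 000 iterations; non-convergence raises with the
final residual).

Dielectric regions: solvent 80, protein interior 8, membrane core 4,
headgroup shells 8, reference environment 1 — all configurable. The
protein region is the union of atom spheres at their input radii; no
solvent-probe reentrant surface and no Stern layer are constructed
(both would be additions, not corrections, at the grid spacings used).
The membrane is an infinite slab: a hydrophobic core of half-thickness
(total/2 − 2 Å) and 2 Å headgroup shells on either side, positioned
per frame from marker atoms (midplane = mean z of terminal methyls;
thickness = difference of leaflet-mean phosphorus z). Frames without
membrane markers are legal and give a protein+solvent-only map, so the
machinery reuses unchanged for soluble proteins.

Focusing: a coarse solve (default 1.5 Å spacing, 10 Å padding) over the
whole frame supplies interpolated boundary values for a fine solve
(default 0.5 Å) on a box centred on the site of interest (half-extent
8 Å). Validation on a uniform medium: the solved potential matches the
Coulomb form within 0.8% over 3–10 Å at 0.5 Å spacing and the screened
(Yukawa) form within 1.1%; the Born-ion solvation energy is within ~4%
of the closed form at 0.5 Å and converges monotonically with grid
refinement (13% → 7% → 4% over 2.0/1.0/0.5 Å).

## The thermodynamic cycle

For site s with reference pKa pKa_ref:

    pKa = pKa_ref + ( ΔG_deprot^protein − ΔG_deprot^water ) / (ln 10 · k_BT)

where ΔG_deprot = G(deprotonated) − G(protonated) and G = ½Σqφ from a
PB solve with all charges of that leg. An environment that penalizes
deprotonation relative to water raises the pKa. The protein leg carries
the full frame (all other titratable sites fixed at the current
assignment's charge sets — single-site evaluation, not coupled
multi-site statistical mechanics), the membrane map, and the selected
explicit ions at their valence charges. The water leg is the model
compound: the same residue's atoms at the same coordinates, backbone
atoms beyond Cα removed and all charges zeroed except the titratable
functional group, solvated with its own sphere-union cavity in solvent
dielectric, without membrane or ions.

Two numerical choices make the cycle accurate on a grid. First, both
legs of a site's cycle reuse one fine grid pinned to the site centre,
so the (large) grid self-energy of the spread charges cancels exactly
in the double difference; this requires focus_half_extent ≤ padding and
is enforced. Second, the model compound keeps its own low-dielectric
cavity rather than sitting in a literally uniform ε=80 medium — this
is what makes the cycle close exactly (pKa = pKa_ref to < 1e-9) when a
frame contains nothing but the compound itself.

Titratable-site charge sets are data, not code: the packaged default
localizes the ±1 proton charge on the functional-group atom (Asp CG,
Glu CD, Lys NZ; His spreads +0.5/+0.5 over ND1/NE2 in the charged form
and is neutral in its default ε-tautomer). Alternative charge models
drop in through `identify_titratable_sites(charge_sets=...)` or the
PDB parameter YAML.

## Ensemble averaging and iteration

A site's reported pKa is the mean ± SD over every (frame, equivalent
subunit) sample — e.g. five snapshots × three chains = n = 15; failed
samples are dropped with a warning and reduce n. Subunit equivalence is
by residue name + number across chains.

The iteration starts from the default assignment (Asp/Glu
deprotonated, His neutral, Lys protonated). After each round, every
deprotonated Asp/Glu/His whose mean pKa exceeds the state's relevant pH
(7.4 closed, 5.5 open/desensitized) is protonated and every protonated
Lys below it is deprotonated; all qualifying sites switch in the same
round by default (a one-site-per-round mode exists for the conservative
reading). Because the rules never reverse a switch, frozen-frame
iteration is monotone and terminates; max_rounds (default 10) guards
the re-simulated case, reporting converged=False rather than raising.
Reported values follow the last-round-before-adjustment rule: a
switched site keeps the estimate from the round whose table triggered
its (latest) switch.

## Sensor analysis

Protonation fractions use f(prot) = 1/(1+10^(pH−pKa)) at five
conditions: closed at pH 7.4, start/end of activation at pH 6.0
(closed-/open-state pKa), start/end of steady-state desensitization at
pH 6.8 (closed-/desensitized-state pKa). Drivers change f by ≥ 0.15
(absolute, so deprotonation counts) already at acidification; stabilizers
change it relative to the closed state once the new conformation is
reached. The 0.15 threshold is configurable and acknowledged as an
arbitrary limit.

Ranking combines two criteria into an explicit score (the published
procedure names the criteria but not the formula, so the weighting here
is this package's documented interpretation): criterion 1 — both state
pKas within [5, 8], or one below 5 with the other above 8; criterion
2 — |ΔpKa| min–max scaled across the analysed residues. score =
w_range·flag + w_delta·scaled (defaults 1/1), descending, ties broken
by |ΔpKa| then site id. Note that criterion 1, taken literally, is not
satisfied by a residue whose pKa moves from far below the window to
inside it; such residues outrank in-range distractors only through the
|ΔpKa| tie-break at equal score. The weighting is deliberately exposed
rather than tuned.

## Functional analysis

Activation curves are fitted to I = I_max/[1+(10^−pH50/10^−pH)^nH] by
least squares (starting values: midpoint from the linear-interpolated
half-maximum crossing, nH = 1, I_max = max response; bounds keep nH in
(0, 10] and the midpoint within the data span ± 1). SSD availability
curves use the mirrored Hill form — response falling as the
conditioning pH falls — with the midpoint reported as pHD50. Standard
errors are asymptotic (from the fit covariance); ΔpH50 errors and
mutant-cycle coupling errors combine in quadrature, and non-additivity
is declared at |coupling| > 1.96·SE by default.

Effect classes bin |ΔpH50| with closed lower edges: weak [0.08, 0.2),
moderate [0.2, 0.3), strong ≥ 0.3; a mutation is functionally important
when |ΔpH50| ≥ 0.2 or |ΔpHD50| ≥ 0.15. Property regressions are
ordinary least squares of pH50/pHD50 on one scale at a time, requiring
≥ 4 distinct substitutions (the source material is ambiguous between
"more than four" and panels of exactly four; ≥ 4 is the default and
configurable), reporting raw two-sided p-values (no multiple-testing
correction by default; Holm available as a flag). The 12 packaged
scales (bulkiness, flexibility, H-bond donor/acceptor counts,
hydropathy, polarity, α/β/turn/coil propensities, size, surface) are
transcribed from the standard literature sources cited in the CSV
header and are user-replaceable.

## Synthetic data: what it emulates and what it does not

`make_toy_membrane_system` builds frames of titratable side-chain
fragments (a neutral Cβ plus the charged functional atom), point
background charges, charge-free lipid marker atoms realizing an exact
slab, and ions; `jitter_frames` emulates trajectory snapshots with
zero-mean Gaussian coordinate noise (frame 0 unperturbed, labels
0/2/4/6/8 mimicking ns time points). These capture the electrostatic
structure of the problem — charge–charge coupling, cavity desolvation,
slab dielectrics, explicit ions, conformational spread — but not real
protein features: no backbone dipoles or partial-charge distributions,
no correlated conformational motion, no lipid chemistry, no real
side-chain rotamers. Passing tests therefore validate the solver,
cycle, averaging and protocol logic, not force-field-level accuracy on
real proteins.

The independent ground truth is `microstate_titration_oracle`: for ≤ 3
sites it enumerates all protonation microstates with energy
Σᵢ ln10·k_BT·(pH − pKa_ref,i)·xᵢ + Σ_{i<j} k_c qᵢqⱼ/(ε_r r_ij)
(acid charge x−1, base charge x), Boltzmann-averages per-site
protonation, and interpolates the apparent pKa½. On a GLU–LYS pair at
6 Å in ε 80 the full PB pipeline agrees with the oracle to < 0.01 pKa
units, far inside the 0.3-unit acceptance band.

## Problem sizes and numerical defaults

The shipped tests and the acceptance script use single-charge grids of
≈ 50³–60³ nodes at 0.5 Å, toy-system cycles with 1.0 Å coarse / 0.5 Å
fine focusing, 2–5-frame ensembles, 100 Hill-recovery curves and 500
regression-null panels — sizes chosen so the whole validation battery
completes in minutes on one core while leaving each check's error
margin an order of magnitude inside its tolerance. CG tolerance 1e-6
(relative residual), trilinear interpolation everywhere, ties in
ranking broken deterministically, and every random draw flows through
a named, seedable generator, so repeated runs are bit-identical.

## Known limitations

- Linearized PB only; the linearization error analysis quantifies what
  the truncation costs (≈ 0.24 pKa units for a tight salt bridge) but
  the nonlinear solve is out of scope.
- Single-site cycle evaluations with partners fixed by the current
  assignment; true multi-site coupling is available only through the
  ≤ 3-site oracle.
- Sphere-union molecular surface (no reentrant surface, no Stern
  layer); adequate at 0.5 Å spacing for the validation systems, but a
  known systematic for deeply buried sites.
- The membrane is a flat slab — no curvature, deformation or
  lipid-species-specific dielectric profiles.
- PDB input assigns charges from a minimal parameter table (full ±1 on
  the functional atom, zero elsewhere); for production work supply PQR
  files with force-field charges, which bypass the table entirely.
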