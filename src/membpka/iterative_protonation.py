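"""Round-based protonation-state iteration.

The pKa of a site depends on the charges of its neighbours, which in turn
depend on their protonation states.  The protocol resolves this
self-consistency iteratively: round 1 computes ensemble pKas with every
site in its default form (acids deprotonated, His neutral, Lys
protonated); after each round, Asp/Glu/His sites whose mean pKa lies
above the state's relevant pH are switched to protonated and Lys sites
whose mean pKa lies below it to deprotonated; rounds repeat with the
updated assignment until nothing changes.

The relevant pH is state-specific: 7.4 for the closed state, 5.5 for the
open and desensitized states (configurable).  Reported pKas follow the
"last round before adjustment" rule: a site that changed state keeps the
estimate from the round whose table triggered its (latest) adjustment;
untouched sites report the final round.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

from .constants import PhysicalConstants
from .pka_engine import SolverSettings, StatePKaTable, compute_state_pka_table
from .structure_io import FrameEnsemble, ProtonationAssignment, TitratableSite

RELEVANT_PH: dict[str, float] = {"closed": 7.4, "open": 5.5, "desensitized": 5.5}

ACID_LIKE = {"ASP", "GLU", "HIS"}  # protonate when pKa > relevant pH
BASE_LIKE = {"LYS"}  # deprotonate when pKa < relevant pH


@dataclass
class RoundRecord:
    round_index: int
    pka_table: StatePKaTable
    assignment_before: ProtonationAssignment
    assignment_after: ProtonationAssignment
    changed_sites: list[str] = field(default_factory=list)


@dataclass
class ConvergenceReport:
    rounds: list[RoundRecord]
    converged: bool
    final_pka_table: StatePKaTable

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)


def update_assignment(
    pka_table: StatePKaTable,
    relevant_ph: float,
    assignment: ProtonationAssignment,
    mode: str = "all",
) -> tuple[ProtonationAssignment, list[str]]:
    """Switch sites whose mean pKa is on the wrong side of the relevant pH.

    Deprotonated Asp/Glu/His with mean pKa > relevant_ph become
    protonated; protonated Lys with mean pKa < relevant_ph become
    deprotonated.  ``mode='all'`` switches every qualifying site in the
    same round; ``mode='single'`` switches only the site with the largest
    |pKa − relevant_ph| (the conservative one-at-a-time variant).
    """
    if mode not in {"all", "single"}:
        raise ValueError(f"unknown update mode {mode!r}")
    candidates: list[tuple[float, str, str]] = []  # (priority, site, new_state)
    for sid, est in pka_table.estimates.items():
        if sid not in assignment.states:
            raise KeyError(f"site {sid} in pKa table but absent from assignment")
        current = assignment[sid]
        if est.residue_name in ACID_LIKE and current == "deprotonated" and est.mean_pka > relevant_ph:
            candidates.append((est.mean_pka - relevant_ph, sid, "protonated"))
        elif est.residue_name in BASE_LIKE and current == "protonated" and est.mean_pka < relevant_ph:
            candidates.append((relevant_ph - est.mean_pka, sid, "deprotonated"))
    if mode == "single" and candidates:
        candidates = [max(candidates)]
    new = assignment.copy()
    changed = []
    for _, sid, new_state in sorted(candidates, key=lambda t: t[1]):
        new.states[sid] = new_state
        changed.append(sid)
    return new, changed


def run_iteration(
    ensemble_provider: Callable[[ProtonationAssignment], FrameEnsemble],
    sites: Sequence[TitratableSite],
    constants: PhysicalConstants,
    settings: SolverSettings | None = None,
    relevant_ph: float | None = None,
    max_rounds: int = 10,
    mode: str = "all",
    average_subunits: bool = True,
) -> ConvergenceReport:
    """Run rounds of (ensemble pKa -> assignment update) to convergence.

    ``ensemble_provider`` maps an assignment to a FrameEnsemble — an MD
    engine re-run, a loader of precomputed per-round ensembles, or the
    synthetic jitter generator (which may ignore the assignment).
    Non-convergence within ``max_rounds`` is reported (converged=False),
    not raised.
    """
    assignment = ProtonationAssignment.default_for(sites)
    rounds: list[RoundRecord] = []
    last_changed_round: dict[str, int] = {}
    converged = False
    state_label = None

    for round_index in range(1, max_rounds + 1):
        ensemble = ensemble_provider(assignment)
        state_label = ensemble.state_label
        ph = RELEVANT_PH[state_label] if relevant_ph is None else relevant_ph
        table = compute_state_pka_table(
            ensemble,
            sites,
            assignment,
            constants,
            settings,
            round_index=round_index,
            average_subunits=average_subunits,
        )
        new_assignment, changed = update_assignment(table, ph, assignment, mode=mode)
        rounds.append(
            RoundRecord(
                round_index=round_index,
                pka_table=table,
                assignment_before=assignment.copy(),
                assignment_after=new_assignment.copy(),
                changed_sites=list(changed),
            )
        )
        for sid in changed:
            last_changed_round[sid] = round_index
        assignment = new_assignment
        if not changed:
            converged = True
            break

    final = _reported_table(rounds, last_changed_round, state_label)
    return ConvergenceReport(rounds=rounds, converged=converged, final_pka_table=final)


def _reported_table(
    rounds: Sequence[RoundRecord],
    last_changed_round: dict[str, int],
    state_label: str,
) -> StatePKaTable:
    """Apply the last-round-before-adjustment reporting rule."""
    by_index = {r.round_index: r.pka_table for r in rounds}
    final_round = rounds[-1].round_index
    estimates = {}
    for sid, est in by_index[final_round].estimates.items():
        src = by_index[last_changed_round.get(sid, final_round)]
        estimates[sid] = src.estimates[sid]
    return StatePKaTable(state=state_label, estimates=estimates, round_index=final_round)
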