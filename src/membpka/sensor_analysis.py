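"""pH-sensor ranking, Henderson-Hasselbalch protonation fractions and
driver/stabilizer classification.

Candidate pH sensors are ranked from state pKa tables by two criteria:
(1) both the closed-state and target-state pKa fall inside the relevant
pH window [5, 8] (or straddle it completely — one below 5, the other
above 8), and (2) the magnitude of the pKa change between the states,
min-max scaled across the analyzed residues.

Protonation fractions f(prot) = 1/(1 + 10^(pH − pKa)) are tabulated at
five (state, pH) conditions: closed at pH 7.4, start/end of activation
at pH 6.0 (closed/open pKa), start/end of steady-state desensitization
at pH 6.8 (closed/desensitized pKa).  A residue whose f(prot) changes by
at least 0.15 at the moment of acidification may drive the transition
("driver"); one whose f(prot) changes only once the new conformation is
reached may stabilize it ("stabilizer").
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

DEFAULT_PH_CONDITIONS: dict[str, float] = {
    "closed": 7.4,
    "activation": 6.0,
    "ssd": 6.8,
}
DEFAULT_RANGE_BOUNDS = (5.0, 8.0)
DRIVER_STABILIZER_THRESHOLD = 0.15

FPROT_COLUMNS = (
    "f_closed",
    "f_start_activation",
    "f_end_activation",
    "f_start_ssd",
    "f_end_ssd",
)


def protonation_fraction(pka, ph):
    """Henderson-Hasselbalch protonated fraction f = 1/(1 + 10^(pH − pKa))."""
    pka = np.asarray(pka, dtype=float)
    ph = np.asarray(ph, dtype=float)
    out = 1.0 / (1.0 + 10.0 ** (ph - pka))
    if out.ndim == 0:
        return float(out)
    return out


def _as_pka_map(table) -> dict[str, float]:
    """Accept a StatePKaTable or a plain site -> pKa mapping."""
    if hasattr(table, "estimates"):
        return {sid: est.mean_pka for sid, est in table.estimates.items()}
    return dict(table)


def fprot_table(
    pka_closed,
    pka_open,
    pka_desensitized,
    ph_conditions: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Protonated fractions at the five (state, pH) conditions per site.

    Inputs are per-state pKa tables (StatePKaTable or site -> pKa maps).
    Sites missing from any state get NaN fractions for the affected
    columns and ``complete=False``.
    """
    ph = dict(DEFAULT_PH_CONDITIONS)
    if ph_conditions:
        ph.update(ph_conditions)
    closed = _as_pka_map(pka_closed)
    opened = _as_pka_map(pka_open)
    desens = _as_pka_map(pka_desensitized)
    sites = sorted(set(closed) | set(opened) | set(desens))
    rows = []
    for sid in sites:
        c, o, d = closed.get(sid), opened.get(sid), desens.get(sid)
        row = {
            "site": sid,
            "f_closed": protonation_fraction(c, ph["closed"]) if c is not None else np.nan,
            "f_start_activation": protonation_fraction(c, ph["activation"]) if c is not None else np.nan,
            "f_end_activation": protonation_fraction(o, ph["activation"]) if o is not None else np.nan,
            "f_start_ssd": protonation_fraction(c, ph["ssd"]) if c is not None else np.nan,
            "f_end_ssd": protonation_fraction(d, ph["ssd"]) if d is not None else np.nan,
            "complete": c is not None and o is not None and d is not None,
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in FPROT_COLUMNS:
        df[col + "_2dp"] = df[col].round(2)
    return df


@dataclass
class SensorScore:
    site: str
    pka_closed: float
    pka_target: float
    in_range: bool
    delta_pka: float
    scaled_delta: float
    score: float
    rank: int


def rank_sensors(
    pka_closed,
    pka_target,
    weights: tuple[float, float] = (1.0, 1.0),
    range_bounds: tuple[float, float] = DEFAULT_RANGE_BOUNDS,
) -> pd.DataFrame:
    """Rank candidate pH sensors for one transition.

    score = w_range·[criterion 1] + w_delta·scaled|ΔpKa|, descending;
    ties broken by |ΔpKa| then site id.  Criterion 1 holds when both
    pKas lie within ``range_bounds`` or when they completely straddle it.
    """
    closed = _as_pka_map(pka_closed)
    target = _as_pka_map(pka_target)
    sites = sorted(set(closed) & set(target))
    if not sites:
        raise ValueError("no common sites between the two pKa tables")
    lo, hi = range_bounds
    w_range, w_delta = weights

    rows = []
    for sid in sites:
        c, t = closed[sid], target[sid]
        both_in = (lo <= c <= hi) and (lo <= t <= hi)
        straddle = (c < lo and t > hi) or (t < lo and c > hi)
        rows.append(
            {
                "site": sid,
                "pka_closed": c,
                "pka_target": t,
                "in_range": bool(both_in or straddle),
                "delta_pka": t - c,
            }
        )
    df = pd.DataFrame(rows)
    mags = df["delta_pka"].abs()
    span = mags.max() - mags.min()
    df["scaled_delta"] = 0.0 if span < 1e-12 else (mags - mags.min()) / span
    df["score"] = w_range * df["in_range"].astype(float) + w_delta * df["scaled_delta"]
    df = df.sort_values(
        by=["score", "delta_pka", "site"],
        key=lambda s: s.abs() if s.name == "delta_pka" else s,
        ascending=[False, False, True],
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def classify_driver_stabilizer(
    fprot: pd.DataFrame,
    transition: str,
    threshold: float = DRIVER_STABILIZER_THRESHOLD,
) -> pd.DataFrame:
    """Label drivers and stabilizers of one transition from an fprot table.

    driver: |f(start) − f(closed 7.4)| >= threshold — the protonation
    change happens at the moment of acidification, while the channel is
    still closed.  stabilizer: |f(end) − f(closed 7.4)| >= threshold —
    the change materializes once the new conformation is reached.
    Deprotonation counts too (absolute differences).  Incomplete rows
    are skipped with a warning.
    """
    if transition not in {"activation", "ssd"}:
        raise ValueError(f"unknown transition {transition!r}")
    start_col = f"f_start_{transition}"
    end_col = f"f_end_{transition}"
    rows = []
    for _, r in fprot.iterrows():
        if not np.isfinite([r["f_closed"], r[start_col], r[end_col]]).all():
            import warnings

            warnings.warn(f"skipping incomplete fprot row for site {r['site']}", stacklevel=2)
            continue
        d_start = r[start_col] - r["f_closed"]
        d_end = r[end_col] - r["f_closed"]
        rows.append(
            {
                "site": r["site"],
                "transition": transition,
                "delta_f_start": d_start,
                "delta_f_end": d_end,
                "driver": bool(abs(d_start) >= threshold),
                "stabilizer": bool(abs(d_end) >= threshold),
            }
        )
    return pd.DataFrame(rows)


def load_published_fprot_table(path: str | Path | None = None) -> pd.DataFrame:
    """The published hASIC1a protonation-fraction table, in fprot layout.

    Returns columns site, f_closed, f_start_activation, f_end_activation,
    f_start_ssd, f_end_ssd, domain, complete — directly consumable by
    :func:`classify_driver_stabilizer`.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "asic1a_protonation_fractions.csv"
    df = pd.read_csv(path, comment="#")
    df["complete"] = True
    return df
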