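"""Hill fits, effect classification, mutant-cycle additivity and
side-chain property regressions for electrophysiology panels.

Activation curves (normalized peak current vs stimulation pH) are fitted
to the Hill equation

    I = I_max / [1 + (10^-pH50 / 10^-pH)^nH]

and steady-state desensitization (SSD) availability curves to the
analogous mirrored form, whose midpoint is named pHD50.  Mutant effects
are expressed as ΔpH50 = pH50(mutant) − pH50(WT) and binned into
weak/moderate/strong classes; double-mutant cycles test additivity; and
when ≥4 substitutions of one position were measured, pH50/pHD50 is
regressed on each of 12 side-chain property scales.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

SCALE_NAMES = (
    "bulkiness",
    "flexibility",
    "hydrogen_acceptor",
    "hydrogen_donor",
    "hydropathy",
    "polarity",
    "alpha_propensity",
    "beta_propensity",
    "turn_propensity",
    "coil_propensity",
    "size",
    "surface",
)


@dataclass
class DoseResponseCurve:
    """pH series with normalized current responses (peak / max peak)."""

    ph: np.ndarray
    response: np.ndarray
    sem: np.ndarray | None = None
    transition: str = "activation"
    n: int = 1

    def __post_init__(self) -> None:
        self.ph = np.asarray(self.ph, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.transition not in {"activation", "ssd"}:
            raise ValueError(f"unknown transition {self.transition!r}")
        if self.ph.shape != self.response.shape:
            raise ValueError("ph and response must have the same shape")


@dataclass
class HillFit:
    """Fitted midpoint (pH50 or pHD50), Hill coefficient and amplitude."""

    ph50: float
    n_h: float
    i_max: float
    se_ph50: float
    se_n_h: float
    se_i_max: float
    transition: str = "activation"
    converged: bool = True
    message: str = ""


@dataclass
class MutantRecord:
    """One mutant's effect relative to same-day WT."""

    label: str
    delta_ph50: float | None = None
    delta_phd50: float | None = None
    sem: float | None = None
    n: int | None = None
    substitution: str | None = None


@dataclass
class EffectClass:
    bin: str  # none / weak / moderate / strong
    functionally_important: bool


@dataclass
class CouplingResult:
    """Double-mutant-cycle coupling Δ(AB) − [Δ(A) + Δ(B)]."""

    coupling: float
    se: float
    non_additive: bool
    z: float = 1.96


@dataclass(frozen=True)
class PropertyScale:
    """One amino-acid property scale over the 20 canonical residues."""

    name: str
    values: Mapping[str, float] = field(hash=False)

    def __post_init__(self) -> None:
        if set(self.values) != CANONICAL_AA:
            missing = CANONICAL_AA - set(self.values)
            extra = set(self.values) - CANONICAL_AA
            raise ValueError(
                f"scale {self.name!r} must cover exactly the 20 canonical amino acids "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )


@dataclass
class RegressionResult:
    scale_name: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def load_property_scales(path: str | Path | None = None) -> dict[str, PropertyScale]:
    """The 12 packaged side-chain property scales (or a user CSV).

    The CSV has an ``amino_acid`` column (one-letter codes) and one
    column per scale; comment lines start with '#'.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "property_scales.csv"
    df = pd.read_csv(path, comment="#")
    df = df.set_index("amino_acid")
    return {
        name: PropertyScale(name=name, values=df[name].to_dict()) for name in df.columns
    }


# ---------------------------------------------------------------------------
# Hill fitting


def _hill_model(ph, ph50, n_h, i_max, sign):
    return i_max / (1.0 + 10.0 ** (sign * n_h * (ph - ph50)))


def _half_max_crossing(ph: np.ndarray, resp: np.ndarray) -> float:
    half = resp.max() / 2.0
    order = np.argsort(ph)
    ph_s, r_s = ph[order], resp[order]
    for i in range(len(ph_s) - 1):
        r0, r1 = r_s[i], r_s[i + 1]
        if (r0 - half) * (r1 - half) <= 0 and r0 != r1:
            return float(ph_s[i] + (half - r0) / (r1 - r0) * (ph_s[i + 1] - ph_s[i]))
    return float(ph_s[len(ph_s) // 2])


def fit_hill(curve: DoseResponseCurve) -> HillFit:
    """Least-squares Hill fit with asymptotic standard errors.

    Starting values: midpoint from the linear-interpolated half-maximum
    crossing, nH = 1, I_max = max response.  A flat curve is an error; a
    non-converged optimization returns a flagged (converged=False) fit.
    """
    ph, resp = curve.ph, curve.response
    if ph.size < 5:
        warnings.warn("fewer than 5 pH points; Hill fit may be unreliable", stacklevel=2)
    if np.ptp(resp) < 1e-9:
        raise FitError("degenerate flat dose-response curve")
    span = (ph.min(), ph.max())
    if not (resp.min() < resp.max() / 2.0 < resp.max()):
        warnings.warn("data do not bracket the half-maximal response", stacklevel=2)

    sign = 1.0 if curve.transition == "activation" else -1.0
    p0 = (_half_max_crossing(ph, resp), 1.0, float(resp.max()))
    try:
        popt, pcov = optimize.curve_fit(
            lambda x, ph50, n_h, i_max: _hill_model(x, ph50, n_h, i_max, sign),
            ph,
            resp,
            p0=p0,
            bounds=([span[0] - 1.0, 1e-3, 1e-6], [span[1] + 1.0, 10.0, 10.0]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        return HillFit(
            ph50=math.nan, n_h=math.nan, i_max=math.nan,
            se_ph50=math.nan, se_n_h=math.nan, se_i_max=math.nan,
            transition=curve.transition, converged=False, message=str(exc),
        )
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    return HillFit(
        ph50=float(popt[0]), n_h=float(popt[1]), i_max=float(popt[2]),
        se_ph50=float(se[0]), se_n_h=float(se[1]), se_i_max=float(se[2]),
        transition=curve.transition,
    )


def delta_ph50(mutant_fit: HillFit, wt_fit: HillFit) -> tuple[float, float]:
    """ΔpH50 = pH50(mutant) − pH50(WT) with SE combined in quadrature."""
    for f, who in ((mutant_fit, "mutant"), (wt_fit, "WT")):
        if not f.converged:
            raise FitError(f"{who} Hill fit did not converge")
    delta = mutant_fit.ph50 - wt_fit.ph50
    se = math.hypot(mutant_fit.se_ph50, wt_fit.se_ph50)
    return delta, se


# ---------------------------------------------------------------------------
# effect classes and mutant cycles

# |ΔpH50| bin edges for activation: weak [0.08, 0.2), moderate [0.2, 0.3),
# strong >= 0.3; a residue is functionally important when |ΔpH50| >= 0.2
# or |ΔpHD50| >= 0.15.
WEAK_EDGE = 0.08
MODERATE_EDGE = 0.2
STRONG_EDGE = 0.3
IMPORTANT_PH50 = 0.2
IMPORTANT_PHD50 = 0.15


def classify_effect(
    delta_ph50: float | None = None, delta_phd50: float | None = None
) -> EffectClass:
    """Bin the pH50 shift and apply the functional-importance thresholds."""
    if delta_ph50 is None and delta_phd50 is None:
        raise ValueError("provide at least one of delta_ph50 / delta_phd50")
    basis = delta_ph50 if delta_ph50 is not None else delta_phd50
    mag = abs(basis)
    if mag >= STRONG_EDGE:
        name = "strong"
    elif mag >= MODERATE_EDGE:
        name = "moderate"
    elif mag >= WEAK_EDGE:
        name = "weak"
    else:
        name = "none"
    important = (delta_ph50 is not None and abs(delta_ph50) >= IMPORTANT_PH50) or (
        delta_phd50 is not None and abs(delta_phd50) >= IMPORTANT_PHD50
    )
    return EffectClass(bin=name, functionally_important=important)


def _record_delta(rec: MutantRecord, transition: str) -> tuple[float, float]:
    val = rec.delta_ph50 if transition == "activation" else rec.delta_phd50
    if val is None:
        raise ValueError(f"record {rec.label!r} lacks a Δ for transition {transition!r}")
    return float(val), float(rec.sem or 0.0)


def mutant_cycle_coupling(
    single_a: MutantRecord,
    single_b: MutantRecord,
    double_ab: MutantRecord,
    transition: str = "activation",
    z: float = 1.96,
) -> CouplingResult:
    """Coupling = Δ(AB) − [Δ(A) + Δ(B)]; non-additive when |coupling| > z·SE.

    Non-additivity of the double mutation relative to the sum of the two
    single mutations is the classic evidence for a residue-residue
    interaction.  Symmetric in A and B.
    """
    da, sa = _record_delta(single_a, transition)
    db, sb = _record_delta(single_b, transition)
    dab, sab = _record_delta(double_ab, transition)
    coupling = dab - (da + db)
    se = math.sqrt(sa**2 + sb**2 + sab**2)
    return CouplingResult(coupling=coupling, se=se, non_additive=abs(coupling) > z * se, z=z)


# ---------------------------------------------------------------------------
# property regression


def property_regression(
    panel: pd.DataFrame,
    scale: PropertyScale,
    response: str = "ph50",
    min_variants: int = 4,
) -> RegressionResult:
    """OLS of the measured response on one side-chain property scale.

    ``panel`` needs a ``substitution`` column (one-letter amino acid) and
    the response column.  At least ``min_variants`` distinct substitutions
    with finite responses are required; a scale that does not vary across
    the panel is a degenerate predictor.
    """
    if response not in panel.columns:
        raise ValueError(f"panel lacks a {response!r} column")
    sub = panel.dropna(subset=[response])
    distinct = sub["substitution"].nunique()
    if distinct < min_variants:
        raise ValueError(
            f"property regression requires at least {min_variants} distinct "
            f"substitutions; got {distinct}"
        )
    x = np.array([scale.values[aa] for aa in sub["substitution"]])
    y = sub[response].to_numpy(dtype=float)
    if np.ptp(x) < 1e-12:
        raise ValueError(f"scale {scale.name!r} has zero variance over this panel")
    res = stats.linregress(x, y)
    return RegressionResult(
        scale_name=scale.name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(y),
    )


def batch_property_regression(
    panel: pd.DataFrame,
    scales: Mapping[str, PropertyScale] | None = None,
    response: str = "ph50",
    holm: bool = False,
) -> pd.DataFrame:
    """One regression per scale (default: all 12 packaged scales).

    Raw p-values by default, mirroring how such screens are usually
    reported; ``holm=True`` adds a Holm-corrected column.
    """
    scales = scales or load_property_scales()
    rows = []
    for name in scales:
        r = property_regression(panel, scales[name], response=response)
        rows.append(
            {
                "scale": r.scale_name,
                "slope": r.slope,
                "intercept": r.intercept,
                "r_squared": r.r_squared,
                "p_value": r.p_value,
                "n": r.n,
            }
        )
    df = pd.DataFrame(rows)
    if holm:
        order = np.argsort(df["p_value"].to_numpy())
        m = len(df)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * df["p_value"].iloc[idx])
            adj[idx] = min(running, 1.0)
        df["p_holm"] = adj
    return df
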