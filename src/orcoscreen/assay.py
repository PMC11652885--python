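"""Cell-based channel-activity analytics.

Covers normalization of luminescence responses against the agonist-only
control, antagonist hit calling at the <=60%-response cutoff, competition
4PL dose-response fitting for IC50, orthosteric/allosteric mechanism
classification from agonist-dependent IC50 shifts, and the repellency index.

The 4PL form is the decreasing logistic

    y = A2 + (A1 - A2) / (1 + 10**((log10(IC50) - x) * p))

with x = log10(concentration), A1 the bottom asymptote, A2 the top
asymptote and p > 0 the Hill slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

RESPONSE_CUTOFF_PCT = 60.0   # secondary response <= 60% -> antagonist hit
AGONIST_LIKE_PCT = 15.0      # primary response >= 15% -> excluded as agonist-like
DEFAULT_FOLD_SHIFT = 1.3     # IC50(150)/IC50(50) threshold for orthosteric call
DEFAULT_R2_THRESHOLD = 0.8


@dataclass(frozen=True)
class DoseResponseCurve:
    """Competition series: replicate % responses per antagonist concentration."""

    compound_id: str
    antagonist_concentrations: tuple[float, ...]
    responses: tuple[tuple[float, ...], ...]  # one replicate tuple per level
    agonist_concentration: float = 100.0

    def __post_init__(self) -> None:
        conc = self.antagonist_concentrations
        if len(conc) != len(self.responses):
            raise ValueError("one replicate set required per concentration")
        if any(c <= 0 for c in conc):
            raise ValueError("concentrations must be strictly positive")
        if list(conc) != sorted(conc):
            raise ValueError("concentrations must be sorted ascending")

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """(log10 concentration, response) pairs over all replicates."""
        xs, ys = [], []
        for c, reps in zip(self.antagonist_concentrations, self.responses):
            for r in reps:
                xs.append(math.log10(c))
                ys.append(r)
        return np.asarray(xs), np.asarray(ys)


@dataclass(frozen=True)
class FourPLFit:
    a1_bottom: float
    a2_top: float
    hill_p: float
    ic50_uM: float
    r_squared: float
    extrapolated: bool = False

    @property
    def pic50(self) -> float:
        return -math.log10(self.ic50_uM * 1e-6)

    def predict(self, conc_uM: np.ndarray | float) -> np.ndarray | float:
        x = np.log10(conc_uM)
        return _four_pl(x, self.a1_bottom, self.a2_top, math.log10(self.ic50_uM), self.hill_p)


@dataclass(frozen=True)
class MechanismCall:
    compound_id: str
    ic50_by_agonist: dict[float, float]
    call: str  # orthosteric | allosteric | indeterminate
    fold_shift: float | None
    reason: str = ""


@dataclass(frozen=True)
class RepellencyResult:
    treatment_landings: int
    control_landings: int

    @property
    def ri(self) -> float:
        return 1.0 - self.treatment_landings / self.control_landings

    @property
    def ri_percent(self) -> float:
        return 100.0 * self.ri


def normalize_response(raw_compound_signal, raw_oa_control_signal) -> float | tuple:
    """Percent response relative to the agonist-only (100%) control.

    Accepts scalars or replicate sequences; replicate input returns
    (mean_pct, se_pct, per_replicate_pct).
    """
    if np.ndim(raw_compound_signal) > 0:
        ctrl = float(np.mean(raw_oa_control_signal)) if np.ndim(raw_oa_control_signal) > 0 \
            else float(raw_oa_control_signal)
        if ctrl <= 0:
            raise ValueError("control signal must be positive")
        pct = 100.0 * np.asarray(raw_compound_signal, dtype=float) / ctrl
        se = float(np.std(pct, ddof=1) / math.sqrt(len(pct))) if len(pct) > 1 else 0.0
        return float(np.mean(pct)), se, tuple(float(v) for v in pct)
    if raw_oa_control_signal <= 0:
        raise ValueError("control signal must be positive")
    return 100.0 * raw_compound_signal / raw_oa_control_signal


def call_antagonist(secondary_response_pct: float, primary_response_pct: float) -> str:
    """Hit call: agonist-like primaries are excluded, then the 60% cutoff applies."""
    if not (math.isfinite(secondary_response_pct) and math.isfinite(primary_response_pct)):
        raise ValueError("responses must be finite")
    if primary_response_pct >= AGONIST_LIKE_PCT:
        return "excluded_agonist_like"
    return "hit" if secondary_response_pct <= RESPONSE_CUTOFF_PCT else "not_hit"


def _four_pl(x, a1, a2, logic50, p):
    return a2 + (a1 - a2) / (1.0 + 10.0 ** ((logic50 - x) * p))


def fit_4pl(curve: DoseResponseCurve) -> FourPLFit:
    """Least-squares 4PL fit with deterministic multi-start initialization."""
    x, y = curve.flat()
    if len(set(curve.antagonist_concentrations)) < 4:
        raise ValueError("at least 4 distinct concentrations required")
    if np.ptp(y) == 0:
        raise ValueError("responses are all equal: no dose dependence to fit")

    ylo, yhi = float(np.min(y)), float(np.max(y))
    span = yhi - ylo
    xmid = float(np.median(x))
    xlo, xhi = float(np.min(x)), float(np.max(x))
    starts = [
        (ylo, yhi, x0, p0)
        for x0 in (xmid, xlo, xhi, xlo - 2.0, xhi + 2.0)  # allow off-range IC50
        for p0 in (0.5, 1.0, 2.0, 4.0)
    ]
    # asymptotes may lie far outside the observed window when the tested
    # range misses a plateau, so leave them generous
    bounds = (
        [ylo - 20 * span - 100, ylo - 20 * span - 100, float(np.min(x)) - 4, 1e-3],
        [yhi + 20 * span + 100, yhi + 20 * span + 100, float(np.max(x)) + 4, 50.0],
    )
    best, best_sse = None, np.inf
    errors = []
    for p0 in starts:
        try:
            popt, _ = curve_fit(_four_pl, x, y, p0=p0, bounds=bounds, maxfev=20000)
        except Exception as exc:
            errors.append(str(exc))
            continue
        sse = float(np.sum((_four_pl(x, *popt) - y) ** 2))
        if sse < best_sse:
            best, best_sse = popt, sse
    if best is None:
        raise RuntimeError(
            "4PL fit failed from every start; diagnostics: " + "; ".join(errors[:3])
        )
    a1, a2, logic50, p = (float(v) for v in best)
    if a1 > a2:  # decreasing form requires bottom < top
        raise RuntimeError(
            f"4PL fit degenerate for {curve.compound_id}: bottom {a1:.3g} >= top {a2:.3g}"
        )
    sst = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - best_sse / sst if sst > 0 else 0.0
    ic50 = 10.0 ** logic50
    cmin, cmax = min(curve.antagonist_concentrations), max(curve.antagonist_concentrations)
    extrapolated = not (0.1 * cmin <= ic50 <= 10.0 * cmax)
    return FourPLFit(
        a1_bottom=a1, a2_top=a2, hill_p=p, ic50_uM=ic50,
        r_squared=max(0.0, r2), extrapolated=extrapolated,
    )


def classify_mechanism(
    fits: Mapping[float, FourPLFit],
    fold_shift_threshold: float = DEFAULT_FOLD_SHIFT,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    compound_id: str = "",
    required_levels: Sequence[float] = (50.0, 100.0, 150.0),
) -> MechanismCall:
    """Orthosteric vs allosteric call from agonist-dependent IC50 shifts.

    A surmountable (competitive) antagonist shows IC50 rising monotonically
    with agonist concentration; an agonist-independent IC50 indicates
    allosteric action.
    """
    missing = [lvl for lvl in required_levels if lvl not in fits]
    ic50s = {lvl: fits[lvl].ic50_uM for lvl in required_levels if lvl in fits}
    if missing:
        return MechanismCall(compound_id, ic50s, "indeterminate", None,
                             reason=f"missing agonist level(s): {missing}")
    bad = [lvl for lvl in required_levels if fits[lvl].r_squared < r2_threshold]
    if bad:
        return MechanismCall(compound_id, ic50s, "indeterminate", None,
                             reason=f"fit r^2 below {r2_threshold} at level(s): {bad}")
    lo, hi = min(required_levels), max(required_levels)
    fold = ic50s[hi] / ic50s[lo]
    ordered = [ic50s[lvl] for lvl in sorted(required_levels)]
    # tolerate small noise-driven inversions in the monotone-trend check
    monotone_up = all(b >= 0.85 * a for a, b in zip(ordered, ordered[1:]))
    if monotone_up and fold >= fold_shift_threshold:
        call = "orthosteric"
    elif fold < fold_shift_threshold:
        call = "allosteric"
    else:
        call = "indeterminate"
    return MechanismCall(compound_id, ic50s, call, fold)


def repellency_index(treatment_landings: int, control_landings: int) -> RepellencyResult:
    """RI = 1 - T/C (also reported as percent)."""
    if control_landings <= 0:
        raise ValueError("control landings must be > 0")
    if treatment_landings < 0:
        raise ValueError("treatment landings must be >= 0")
    return RepellencyResult(treatment_landings, control_landings)


@dataclass(frozen=True)
class AssayTruth:
    """Ground truth for the synthetic dose-response generator."""

    a1_bottom: float = 20.0
    a2_top: float = 100.0
    hill_p: float = 1.0
    ic50_uM: float = 50.0            # antagonist potency at zero agonist excess
    mechanism: str = "competitive"   # competitive | noncompetitive
    agonist_ec50_uM: float = 50.0

    def ic50_at(self, agonist_uM: float) -> float:
        if self.mechanism == "competitive":
            # Schild-consistent surmountable shift
            return self.ic50_uM * (1.0 + agonist_uM / self.agonist_ec50_uM)
        return self.ic50_uM


def simulate_assay(
    truth: AssayTruth,
    noise_sd_pct: float = 0.0,
    n_replicates: int = 3,
    concentrations_uM: Sequence[float] = (1, 3, 10, 30, 100, 300, 600, 1000),
    agonist_levels_uM: Sequence[float] = (50.0, 100.0, 150.0),
    seed: int = 0,
    compound_id: str = "sim",
) -> dict[float, DoseResponseCurve]:
    """Seeded synthetic competition curves, one per agonist level."""
    if noise_sd_pct < 0:
        raise ValueError("noise sd must be >= 0")
    if truth.mechanism not in ("competitive", "noncompetitive"):
        raise ValueError(f"unknown mechanism {truth.mechanism!r}")
    if truth.a1_bottom >= truth.a2_top or truth.ic50_uM <= 0 or truth.hill_p <= 0:
        raise ValueError("invalid 4PL truth parameters")
    rng = np.random.default_rng(seed)
    conc = tuple(sorted(float(c) for c in concentrations_uM))
    out = {}
    for lvl in agonist_levels_uM:
        ic50 = truth.ic50_at(lvl)
        responses = []
        for c in conc:
            mu = _four_pl(math.log10(c), truth.a1_bottom, truth.a2_top,
                          math.log10(ic50), truth.hill_p)
            reps = mu + rng.normal(0.0, noise_sd_pct, size=n_replicates) \
                if noise_sd_pct > 0 else np.full(n_replicates, mu)
            responses.append(tuple(float(v) for v in reps))
        out[float(lvl)] = DoseResponseCurve(
            compound_id=compound_id,
            antagonist_concentrations=conc,
            responses=tuple(responses),
            agonist_concentration=float(lvl),
        )
    return out
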