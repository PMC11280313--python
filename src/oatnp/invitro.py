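"""In vitro transporter assay analysis.

Two readouts:

* Magnetic-bead binding competition: OAT1 protein on beads carries the
  fluorescent tracer 6-carboxyfluorescein (6-CF, 6 µM); a competing test
  compound displaces tracer and lowers fluorescence.  The normalized shift
  (test − control)/control classifies a compound as a binder when it is at
  or below −0.05.

* 96-well uptake inhibition: cells overexpressing OAT1 take up 10 µM 6-CF;
  a test compound is dosed as a serial dilution (default 2 mM top dose,
  10 points, 2-fold steps) and percent inhibition per concentration feeds a
  four-parameter log-logistic (4PL) fit yielding an IC50 and Hill slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

BINDER_THRESHOLD = -0.05


# ---------------------------------------------------------------------------
# Bead-binding competition
# ---------------------------------------------------------------------------
def normalize_binding_shift(test: float, control: float) -> float:
    """(test − control)/control; control fluorescence must be positive."""
    if control <= 0:
        raise ValueError("control fluorescence must be positive")
    return (test - control) / control


def call_binder(shift: float, threshold: float = BINDER_THRESHOLD) -> bool:
    """Binder iff the normalized downshift is at or below the threshold.

    The boundary counts as a binder: a shift of exactly −0.05 is
    classified as significant displacement.
    """
    if not np.isfinite(shift):
        raise ValueError("shift must be finite")
    return shift <= threshold


@dataclass
class BindingMeasurement:
    compound_id: str
    control_fluorescence: float
    test_fluorescence: float
    normalized_shift: float = field(init=False)
    is_binder: bool = field(init=False)

    def __post_init__(self):
        self.normalized_shift = normalize_binding_shift(
            self.test_fluorescence, self.control_fluorescence
        )
        self.is_binder = call_binder(self.normalized_shift)


# ---------------------------------------------------------------------------
# Uptake inhibition
# ---------------------------------------------------------------------------
def percent_inhibition(
    uptake: float | np.ndarray, vehicle: float, background: float = 0.0
) -> float | np.ndarray:
    """100 × (1 − (uptake − background)/(vehicle − background)).

    Raw values are returned uncapped (may be negative or exceed 100);
    clip for display only.
    """
    if vehicle <= background:
        raise ValueError("vehicle signal must exceed background")
    return 100.0 * (1.0 - (np.asarray(uptake, dtype=float) - background) / (vehicle - background))


def dilution_series(
    top: float = 2e-3, n_points: int = 10, factor: float = 2.0
) -> np.ndarray:
    """Strictly decreasing concentration series (molar), serial dilution."""
    if top <= 0 or factor <= 1 or n_points < 2:
        raise ValueError("invalid dilution series")
    return top / factor ** np.arange(n_points)


def four_pl(conc: np.ndarray, bottom: float, top: float, ic50: float, hill: float) -> np.ndarray:
    """4PL inhibition curve: response rises from bottom to top with dose."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ic50 / conc) ** hill)


@dataclass
class InhibitionFit:
    compound_id: str
    ic50: float | None
    hill: float | None
    bottom: float | None
    top: float | None
    converged: bool
    rmse: float | None = None
    message: str = ""


def fit_inhibition_curve(
    concentrations: np.ndarray,
    inhibition_pct: np.ndarray,
    compound_id: str = "",
    bottom_bounds: tuple[float, float] = (-10.0, 30.0),
    top_bounds: tuple[float, float] = (70.0, 110.0),
    min_response_range: float = 20.0,
) -> InhibitionFit:
    """Least-squares 4PL fit of percent inhibition vs concentration.

    IC50 is bounded to the dosed range extended by one dilution step on
    either side; a response spanning less than *min_response_range* percent
    (flat curve) is flagged "not converged" instead of fitted, as are
    optimizer failures.  Requires >=5 concentration points.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(inhibition_pct, dtype=float)
    if conc.size < 5:
        raise ValueError("need >=5 concentration points")
    if not np.all(np.diff(conc) < 0):
        raise ValueError("concentrations must be strictly decreasing")
    if resp.max() - resp.min() < min_response_range:
        return InhibitionFit(
            compound_id, None, None, None, None, False,
            message=f"flat response (range {resp.max() - resp.min():.1f}%)",
        )
    step = conc[0] / conc[1]
    lo, hi = conc.min() / step, conc.max() * step
    x0 = np.array([
        np.clip(resp.min(), *bottom_bounds),
        np.clip(resp.max(), *top_bounds),
        np.log10(np.sqrt(lo * hi)),
        1.0,
    ])
    lb = np.array([bottom_bounds[0], top_bounds[0], np.log10(lo), 0.1])
    ub = np.array([bottom_bounds[1], top_bounds[1], np.log10(hi), 5.0])
    x0 = np.clip(x0, lb, ub)

    def resid(theta):
        b, t, log_ic50, h = theta
        return four_pl(conc, b, t, 10.0**log_ic50, h) - resp

    try:
        sol = least_squares(resid, x0, bounds=(lb, ub))
    except Exception as exc:  # pragma: no cover - optimizer failure path
        return InhibitionFit(compound_id, None, None, None, None, False, message=str(exc))
    if not sol.success:
        return InhibitionFit(compound_id, None, None, None, None, False, message=sol.message)
    b, t, log_ic50, h = sol.x
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    return InhibitionFit(
        compound_id,
        ic50=float(10.0**log_ic50),
        hill=float(h),
        bottom=float(b),
        top=float(t),
        converged=True,
        rmse=rmse,
    )


def analyze_binding_plate(plate) -> "pd.DataFrame":
    """Binder calls from a long-format plate table.

    *plate* is a DataFrame with columns compound ('control' rows are the
    6-CF-only wells) and fluorescence; replicate wells are averaged.
    """
    import pandas as pd

    ctrl = plate.loc[plate["compound"] == "control", "fluorescence"]
    if ctrl.empty:
        raise ValueError("plate has no control wells")
    f0 = float(ctrl.mean())
    rows = []
    for cmpd, grp in plate[plate["compound"] != "control"].groupby("compound"):
        m = BindingMeasurement(str(cmpd), f0, float(grp["fluorescence"].mean()))
        rows.append(
            {
                "compound": cmpd,
                "control_fluorescence": f0,
                "test_fluorescence": m.test_fluorescence,
                "normalized_shift": m.normalized_shift,
                "is_binder": m.is_binder,
            }
        )
    return pd.DataFrame(rows).set_index("compound").sort_index()
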