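"""Optogenetically evoked post-synaptic response quantification.

The response of a cell is summarized as the baseline-subtracted charge
integrated over a 10-ms post-stimulus window, normalized by membrane
capacitance, across a sweep of laser powers. Each sweep is fit with a Hill
sigmoid ``charge(x) = amp / (1 + (half_power / x) ** hill_slope)``, whose
value at ``x = half_power`` is ``amp / 2`` by construction. Per-cell
coefficients are reported as log2 fold-change against the control-cohort
median. Paired-pulse ratios isolate the second response by subtracting the
averaged single-pulse response from the paired trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "PowerSweep",
    "SigmoidFit",
    "QCRecord",
    "QCThresholds",
    "hill_sigmoid",
    "integrate_charge",
    "fit_sigmoid",
    "param_fold_changes",
    "ppr",
    "qc_pass",
    "read_sweeps_csv",
    "write_sweeps_csv",
]


@dataclass
class PowerSweep:
    cell_id: str
    condition: str  # 'T3' or 'control'
    cm_pf: float
    powers_mw: np.ndarray
    charges: np.ndarray  # pC/pF, one per power

    def __post_init__(self) -> None:
        self.powers_mw = np.asarray(self.powers_mw, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        if self.powers_mw.shape != self.charges.shape:
            raise ValueError("powers and charges must align")
        if np.any(self.powers_mw <= 0):
            raise ValueError("laser powers must be positive")


@dataclass
class SigmoidFit:
    amp: float
    half_power: float
    hill_slope: float
    rss: float
    valid: bool
    message: str = ""


@dataclass
class QCRecord:
    peak_current_pa: float
    rm_variation_pct: float
    holding_current_pa: float
    rs_variation_pct: float


@dataclass(frozen=True)
class QCThresholds:
    min_peak_current_pa: float = 250.0
    max_rm_variation_pct: float = 20.0
    min_holding_current_pa: float = -400.0  # exclusion bound at -70 mV
    max_rs_variation_pct: float = 25.0


def hill_sigmoid(x: np.ndarray, amp: float, half_power: float, hill_slope: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return amp / (1.0 + (half_power / x) ** hill_slope)


def integrate_charge(
    time_s: np.ndarray,
    current: np.ndarray,
    stim_onset_s: float,
    window_s: float = 0.010,
    cm_pf: float = 1.0,
    baseline_s: float = 0.100,
) -> float:
    """Baseline-subtracted trapezoidal charge over the post-stimulus window,
    divided by Cm. Baseline is the mean current over ``baseline_s`` seconds
    preceding stimulus onset."""
    time_s = np.asarray(time_s, dtype=float)
    current = np.asarray(current, dtype=float)
    end = stim_onset_s + window_s
    if end > time_s[-1] + 1e-12:
        raise ValueError(
            f"integration window ends at {end} s but trace ends at {time_s[-1]} s"
        )
    base_sel = (time_s >= stim_onset_s - baseline_s) & (time_s < stim_onset_s)
    baseline = float(current[base_sel].mean()) if base_sel.any() else 0.0
    sel = (time_s >= stim_onset_s) & (time_s <= end)
    q = np.trapezoid(current[sel] - baseline, time_s[sel])
    return float(q / cm_pf)


def fit_sigmoid(sweep: PowerSweep) -> SigmoidFit:
    """Multi-start nonlinear least squares of the Hill sigmoid in log-power
    space; positivity of all three coefficients enforced by fitting their
    logs. Best residual wins; ties go to the smaller slope."""
    x, y = sweep.powers_mw, sweep.charges
    if len(np.unique(x)) < 5:
        return SigmoidFit(np.nan, np.nan, np.nan, np.nan, False, "need >=5 distinct powers")
    logx = np.log(x)
    ymax = max(float(np.max(np.abs(y))), 1e-12)

    def resid(theta: np.ndarray) -> np.ndarray:
        amp, half, slope = np.exp(theta)
        return amp / (1.0 + np.exp(-slope * (logx - np.log(half)))) - y

    best: tuple[float, np.ndarray, float] | None = None
    half_grid = np.quantile(x, [0.25, 0.5, 0.75])
    slope_grid = (0.5, 1.5, 3.0)
    for h0 in half_grid:
        for s0 in slope_grid:
            theta0 = np.log([ymax, h0, s0])
            try:
                res = least_squares(resid, theta0, max_nfev=5000)
            except Exception:
                continue
            rss = float(np.sum(res.fun**2))
            slope = float(np.exp(res.x[2]))
            if best is None or rss < best[0] - 1e-12 or (
                abs(rss - best[0]) <= 1e-12 and slope < best[2]
            ):
                best = (rss, res.x, slope)
    if best is None:
        return SigmoidFit(np.nan, np.nan, np.nan, np.nan, False, "all starts failed")
    rss, theta, _ = best
    amp, half, slope = (float(v) for v in np.exp(theta))
    if not all(np.isfinite([amp, half, slope])):
        return SigmoidFit(amp, half, slope, rss, False, "non-finite coefficients")
    return SigmoidFit(amp=amp, half_power=half, hill_slope=slope, rss=rss, valid=True)


def param_fold_changes(
    fits: Sequence[tuple[str, SigmoidFit]], control_fits: Sequence[SigmoidFit]
) -> pd.DataFrame:
    """Per-cell log2 change of each coefficient vs the control-cohort median.

    Cells with nonpositive coefficients are excluded (flagged in the
    ``excluded`` column)."""
    ctl = [f for f in control_fits if f.valid]
    if not ctl:
        raise ValueError("need >= 1 valid control fit")
    med = {
        "amp": float(np.median([f.amp for f in ctl])),
        "half_power": float(np.median([f.half_power for f in ctl])),
        "hill_slope": float(np.median([f.hill_slope for f in ctl])),
    }
    rows = []
    for cell_id, f in fits:
        vals = {"amp": f.amp, "half_power": f.half_power, "hill_slope": f.hill_slope}
        bad = (not f.valid) or any(v <= 0 for v in vals.values())
        row: dict = {"cell_id": cell_id, "excluded": bad}
        for k, v in vals.items():
            row[f"log2fc_{k}"] = float("nan") if bad else float(np.log2(v / med[k]))
        rows.append(row)
    return pd.DataFrame(rows)


def ppr(
    time_s: np.ndarray,
    paired_trace: np.ndarray,
    single_trace: np.ndarray,
    stim_onset_s: float,
    inter_pulse_s: float = 0.050,
    window_s: float = 0.010,
    cm_pf: float = 1.0,
    baseline_s: float = 0.100,
) -> float:
    """Paired-pulse ratio: second-pulse charge over first-pulse charge.

    The averaged single-pulse trace is subtracted from the paired trace
    before integrating the second response, isolating it from the decaying
    first response. Returns NaN (flag) when the first-pulse charge is ~0.
    """
    q1 = integrate_charge(time_s, single_trace, stim_onset_s, window_s, cm_pf, baseline_s)
    residual = np.asarray(paired_trace, dtype=float) - np.asarray(single_trace, dtype=float)
    q2 = integrate_charge(
        time_s, residual, stim_onset_s + inter_pulse_s, window_s, cm_pf, baseline_s
    )
    if abs(q1) < 1e-12:
        return float("nan")
    return q2 / q1


def qc_pass(
    record: QCRecord, thresholds: QCThresholds = QCThresholds()
) -> tuple[bool, list[str]]:
    """Evaluate whole-cell recording quality criteria; returns (pass,
    failed-criteria names)."""
    failed = []
    if abs(record.peak_current_pa) <= thresholds.min_peak_current_pa:
        failed.append("peak_current")
    if record.rm_variation_pct >= thresholds.max_rm_variation_pct:
        failed.append("rm_variation")
    if record.holding_current_pa < thresholds.min_holding_current_pa:
        failed.append("holding_current")
    if record.rs_variation_pct >= thresholds.max_rs_variation_pct:
        failed.append("rs_variation")
    return (not failed), failed


# ---------------------------------------------------------------------------
# CSV dialect: cell_id,condition,cm_pf,power_mw,charge_pc_per_pf


def read_sweeps_csv(path) -> list[PowerSweep]:
    df = pd.read_csv(path, dtype={"cell_id": str})
    sweeps = []
    for (cell, cond, cm), grp in df.groupby(["cell_id", "condition", "cm_pf"], sort=False):
        sweeps.append(
            PowerSweep(
                cell_id=str(cell),
                condition=str(cond),
                cm_pf=float(cm),
                powers_mw=grp["power_mw"].to_numpy(),
                charges=grp["charge_pc_per_pf"].to_numpy(),
            )
        )
    return sweeps


def write_sweeps_csv(sweeps: Sequence[PowerSweep], path) -> None:
    rows = []
    for s in sweeps:
        for p, c in zip(s.powers_mw, s.charges):
            rows.append((s.cell_id, s.condition, s.cm_pf, p, c))
    pd.DataFrame(
        rows, columns=["cell_id", "condition", "cm_pf", "power_mw", "charge_pc_per_pf"]
    ).to_csv(path, index=False)
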