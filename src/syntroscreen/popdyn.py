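"""Subpopulation-ratio estimation from dual-fluorophore readouts.

Each strain in a two-member coculture carries either a blue (BFP-style,
ex400/em465) or a red (mScarlet-style, ex560/em620) tag. Per-strain,
per-channel calibration lines (intensity = slope * OD + background) are
fitted on monoculture dilution series; coculture channel readings are
then unmixed through the 2x2 slope matrix to per-strain OD estimates and
a blue-strain proportion. Stability across serial passages is quantified
by the final-proportion difference and the Pearson correlation of the
two proportion trajectories on a common relative-time grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

# the dilution ODs used for calibration series in this workflow
CALIBRATION_DILUTION_ODS = (0.95, 0.90, 0.80, 0.66, 0.5, 0.33, 0.20, 0.10, 0.05)
# inoculation-ratio grid (blue:red) at total inoculum OD 0.10
INOCULATION_RATIOS = ("1:20", "1:10", "1:5", "1:2", "1:1", "2:1", "5:1", "10:1", "20:1")
TOTAL_INOCULUM_OD = 0.10


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear fluorescence-vs-OD fit for one strain in one channel."""

    strain_id: str
    channel: str  # 'blue' or 'red'
    slope: float
    background: float
    fit_r2: float
    n_points: int


def fit_calibration(
    dilution_ods, intensities, strain_id: str, channel: str
) -> CalibrationCurve:
    """OLS line intensity = slope * OD + background over a dilution series."""
    od = np.asarray(dilution_ods, dtype=float)
    f = np.asarray(intensities, dtype=float)
    if od.size != f.size:
        raise ValueError("dilution_ods and intensities must align")
    if od.size < 2 or np.unique(od).size < 2:
        raise ValueError("calibration needs >= 2 distinct OD points")
    res = stats.linregress(od, f)
    return CalibrationCurve(
        strain_id=strain_id,
        channel=channel,
        slope=float(res.slope),
        background=float(res.intercept),
        fit_r2=float(res.rvalue**2),
        n_points=int(od.size),
    )


def _slope_matrix(
    curves: dict[tuple[str, str], CalibrationCurve],
    blue_strain: str,
    red_strain: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Build (A, backgrounds): rows = channels (blue, red), cols = strains.

    Cross-channel curves (e.g. the red strain's bleed into the blue
    channel) default to slope 0 when not measured; channel background is
    taken from the same-channel primary curve.
    """
    A = np.zeros((2, 2))
    bg = np.zeros(2)
    strains = (blue_strain, red_strain)
    for i, channel in enumerate(("blue", "red")):
        for j, strain in enumerate(strains):
            curve = curves.get((strain, channel))
            if curve is not None:
                A[i, j] = curve.slope
        primary = curves.get((strains[i], channel))
        if primary is None:
            raise ValueError(
                f"missing calibration for {strains[i]} in its own {channel} channel"
            )
        bg[i] = primary.background
    return A, bg


def unmix(
    f_blue: float,
    f_red: float,
    curves: dict[tuple[str, str], CalibrationCurve],
    blue_strain: str,
    red_strain: str,
) -> tuple[float, float, bool]:
    """Recover (od_blue_strain, od_red_strain) from two channel readings.

    Solves A . od = F - background by least squares; negative components
    are clipped to 0 (flag returned). Raises on a singular slope matrix,
    naming the condition number.
    """
    A, bg = _slope_matrix(curves, blue_strain, red_strain)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(f"calibration slope matrix is singular (cond={cond:.3g})")
    rhs = np.array([f_blue, f_red], dtype=float) - bg
    od, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    clipped = bool(np.any(od < 0))
    od = np.clip(od, 0.0, None)
    return float(od[0]), float(od[1]), clipped


def proportion_trajectory(
    times,
    f_blue,
    f_red,
    curves: dict[tuple[str, str], CalibrationCurve],
    blue_strain: str,
    red_strain: str,
    inoculation_ratio: str | None = None,
) -> pd.DataFrame:
    """Per-timepoint unmixing of a dual-channel time series.

    Returns a frame with columns time, F_blue, F_red, od_blue, od_red,
    proportion_blue (NaN where od_blue + od_red == 0) and, when given,
    the inoculation-ratio label attached for reporting.
    """
    t = np.asarray(times, dtype=float)
    fb = np.asarray(f_blue, dtype=float)
    fr = np.asarray(f_red, dtype=float)
    if not (t.size == fb.size == fr.size):
        raise ValueError("channel series must share the time grid")
    rows = []
    n_clipped = 0
    for ti, fbi, fri in zip(t, fb, fr):
        ob, orr, clip = unmix(fbi, fri, curves, blue_strain, red_strain)
        n_clipped += clip
        total = ob + orr
        prop = ob / total if total > 0 else np.nan
        rows.append((ti, fbi, fri, ob, orr, prop))
    if n_clipped:
        logger.info("unmixing clipped negative ODs at %d timepoint(s)", n_clipped)
    df = pd.DataFrame(
        rows, columns=["time", "F_blue", "F_red", "od_blue", "od_red", "proportion_blue"]
    )
    if inoculation_ratio is not None:
        df["inoculation_ratio"] = inoculation_ratio
    return df


def stability_compare(
    pass1: pd.DataFrame,
    pass2: pd.DataFrame,
    stability_tolerance: float = 0.15,
) -> dict:
    """Compare the proportion trajectory across two serial passages.

    final_delta = |p_blue(end of pass 1) - p_blue(end of pass 2)|;
    trend_corr = Pearson correlation of the two trajectories linearly
    interpolated onto the common relative-time grid (NaN when fewer than
    3 common timepoints or a trajectory is constant). A composition is
    classified 're-established' when final_delta <= stability_tolerance.
    """
    p1 = pass1.dropna(subset=["proportion_blue"])
    p2 = pass2.dropna(subset=["proportion_blue"])
    if len(p1) == 0 or len(p2) == 0:
        raise ValueError("both passages need proportion estimates")
    t1 = p1["time"].to_numpy() - p1["time"].min()
    t2 = p2["time"].to_numpy() - p2["time"].min()
    y1 = p1["proportion_blue"].to_numpy()
    y2 = p2["proportion_blue"].to_numpy()

    final_delta = float(abs(y1[-1] - y2[-1]))

    lo, hi = max(t1.min(), t2.min()), min(t1.max(), t2.max())
    grid = np.union1d(t1, t2)
    grid = grid[(grid >= lo) & (grid <= hi)]
    trend_corr = np.nan
    if grid.size >= 3:
        g1 = np.interp(grid, t1, y1)
        g2 = np.interp(grid, t2, y2)
        if np.std(g1) > 0 and np.std(g2) > 0:
            trend_corr = float(np.corrcoef(g1, g2)[0, 1])
    return {
        "final_delta": final_delta,
        "trend_corr": trend_corr,
        "re_established": final_delta <= stability_tolerance,
    }


def calibration_table(curves) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "strain_id": c.strain_id,
                "channel": c.channel,
                "slope": c.slope,
                "background": c.background,
                "r2": c.fit_r2,
                "n": c.n_points,
            }
            for c in (curves.values() if isinstance(curves, dict) else curves)
        ]
    )


def read_calibration_table(path) -> dict[tuple[str, str], CalibrationCurve]:
    df = pd.read_csv(path, comment="#")
    curves = {}
    for r in df.itertuples():
        curves[(str(r.strain_id), str(r.channel))] = CalibrationCurve(
            strain_id=str(r.strain_id),
            channel=str(r.channel),
            slope=float(r.slope),
            background=float(r.background),
            fit_r2=float(r.r2),
            n_points=int(r.n),
        )
    return curves
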