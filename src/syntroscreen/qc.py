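"""Quality control for endpoint growth screens.

The cascade mirrors how a robotic coculture screen is reduced to an
analyzable set: blank correction of the 0 h -> 48 h OD change, robust
replicate-spread flags (scaled MAD), contamination detection in blanks
and strict-auxotroph monocultures, plate positional-bias detection
(edge-vs-interior contrast and row/column median polish), and a Z-factor
activity-range gate against the fittest constituent monoculture.

Flags gate inclusion; they never adjust the data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plate_model import Config, QCFlag, is_edge

logger = logging.getLogger(__name__)


@dataclass
class ConditionSummary:
    """Replicate summary of blank-corrected growth for one condition."""

    condition_id: str
    n: int
    mean_od: float
    sd_od: float
    median_od: float
    mad_od: float  # scaled MAD
    flags: list[QCFlag] = field(default_factory=list)


@dataclass
class QCResult:
    wells: pd.DataFrame          # all wells with growth values
    kept: pd.DataFrame           # wells surviving hard well-level flags
    flags: list[QCFlag]
    strict_auxotrophs: set[str]  # strain_ids inferred strict from SM medians
    bias_dropped_conditions: set[str]  # assay-level positional-bias drops


def summarize(values, condition_id: str, mad_scale: float = 1.4826) -> ConditionSummary:
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError(f"no replicates for condition {condition_id}")
    return ConditionSummary(
        condition_id=condition_id,
        n=int(x.size),
        mean_od=float(np.mean(x)),
        sd_od=float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        median_od=float(np.median(x)),
        mad_od=float(mad_scale * np.median(np.abs(x - np.median(x)))),
    )


# ---------------------------------------------------------------- blanks

def blank_correct(tidy: pd.DataFrame, config: Config) -> tuple[pd.DataFrame, list[QCFlag]]:
    """Collapse the tidy table to one row per well with a growth value.

    growth = od600(t_end) - od600(t0) - median(blank deltas on the same
    plate), floored at 0. Both the raw delta and the corrected growth are
    retained. Plates lacking blanks keep the raw delta and receive a
    warning flag. Wells missing either timepoint are dropped.
    """
    flags: list[QCFlag] = []
    tidy = tidy.copy()
    # blank/mono rows carry empty strain fields, which CSV round trips as
    # NaN; normalize so the pivot below does not drop them from its index
    for col in ("strain_1", "strain_2", "batch"):
        tidy[col] = tidy[col].fillna("")
    t0, t_end = float(tidy["time"].min()), float(tidy["time"].max())
    if t0 == t_end:
        raise ValueError("need at least two timepoints for endpoint growth")

    wide = tidy.pivot_table(
        index=["plate_id", "batch", "well", "row", "col", "condition_id", "kind",
               "strain_1", "strain_2"],
        columns="time",
        values="od600",
        aggfunc="first",
    ).reset_index()
    wide = wide.rename(columns={t0: "od_t0", t_end: "od_t_end"})
    n_missing = int(wide[["od_t0", "od_t_end"]].isna().any(axis=1).sum())
    if n_missing:
        logger.warning("%d well(s) missing a timepoint, dropped", n_missing)
        wide = wide.dropna(subset=["od_t0", "od_t_end"])
    wide["delta"] = wide["od_t_end"] - wide["od_t0"]

    blank_med = (
        wide[wide["kind"] == "blank"].groupby("plate_id")["delta"].median()
    )
    corrections = wide["plate_id"].map(blank_med)
    for plate in sorted(set(wide["plate_id"]) - set(blank_med.index)):
        flags.append(
            QCFlag(
                flag_kind="contamination",
                scope="assay",
                detail="no blank wells on plate; raw delta used",
                plate_id=plate,
                hard=False,
            )
        )
        logger.warning("plate %s has no blanks; using raw delta", plate)
    wide["growth"] = (wide["delta"] - corrections.fillna(0.0)).clip(lower=0.0)
    return wide.reset_index(drop=True), flags


# --------------------------------------------------- auxotroph classification

def classify_auxotroph(
    od_sm: float,
    od_parent_sm: float,
    od_sc: float,
    od_parent_sc: float,
    config: Config | None = None,
) -> str:
    """Classify a strain from minimal- vs complete-medium growth.

    'auxotroph' iff SM growth is strictly below the threshold fraction
    (default 20%) of the prototrophic parent's AND the strain still grows
    on complete medium (>= sc_growth_threshold of parent). Everything
    else is 'leaky_or_prototroph'.
    """
    config = config or Config()
    if od_parent_sm <= 0 or od_parent_sc <= 0:
        raise ValueError("parent ODs must be positive")
    poor_sm = od_sm < config.auxotroph_fraction_threshold * od_parent_sm
    grows_sc = od_sc >= config.sc_growth_threshold * od_parent_sc
    return "auxotroph" if (poor_sm and grows_sc) else "leaky_or_prototroph"


# ------------------------------------------------------------- spread flags

def scaled_mad(x, scale: float = 1.4826) -> float:
    x = np.asarray(x, dtype=float)
    return float(scale * np.median(np.abs(x - np.median(x))))


def mad_spread_flags(
    replicates,
    k: float = 3.0,
    scale: float = 1.4826,
    fallback_margin: float = 0.05,
) -> np.ndarray:
    """Flag replicates deviating from the median by more than k*scaled-MAD.

    If the MAD degenerates to 0 (identical replicates plus outliers), the
    fallback flags values farther than ``fallback_margin`` from the
    median. With fewer than 3 replicates nothing is flagged (the caller
    records an assay-level warning).
    """
    x = np.asarray(replicates, dtype=float)
    if x.size < 3:
        return np.zeros(x.size, dtype=bool)
    med = np.median(x)
    mad = scale * np.median(np.abs(x - med))
    if mad == 0:
        return np.abs(x - med) > fallback_margin
    return np.abs(x - med) > k * mad


def loo_spread_flags(
    replicates,
    k: float = 3.0,
    scale: float = 1.4826,
    fallback_margin: float = 0.05,
) -> np.ndarray:
    """Leave-one-out spread flags: test each replicate against the rest.

    Plain MAD over n=4 replicates has breakdown point 1 — two coincident
    outliers (e.g. two contaminated wells in one condition) inflate the
    MAD and mask each other. Holding each value out and testing its
    deviation from the *remaining* replicates' median against
    k*scale*MAD(rest) (floored at ``fallback_margin``) recovers the
    two-outlier case while agreeing with the plain rule on single
    outliers.
    """
    x = np.asarray(replicates, dtype=float)
    if x.size < 4:
        return np.zeros(x.size, dtype=bool)
    out = np.zeros(x.size, dtype=bool)
    for i in range(x.size):
        rest = np.delete(x, i)
        med = np.median(rest)
        mad = scale * np.median(np.abs(rest - med))
        thr = max(k * mad, fallback_margin)
        out[i] = abs(x[i] - med) > thr
    return out


def replicate_spread_flags(wells: pd.DataFrame, config: Config) -> list[QCFlag]:
    """Per-condition robust outlier flags on blank-corrected growth."""
    flags: list[QCFlag] = []
    for cid, grp in wells[wells["kind"] != "blank"].groupby("condition_id"):
        if len(grp) < 3:
            flags.append(
                QCFlag(
                    flag_kind="replicate_spread",
                    scope="assay",
                    detail=f"only {len(grp)} replicate(s); spread check skipped",
                    condition_id=str(cid),
                    hard=False,
                )
            )
            continue
        mask = mad_spread_flags(
            grp["growth"].to_numpy(), config.mad_k, config.mad_scale,
            config.blank_margin,
        ) | loo_spread_flags(
            grp["growth"].to_numpy(), config.mad_k, config.mad_scale,
            config.blank_margin,
        )
        for (_, row), bad in zip(grp.iterrows(), mask):
            if bad:
                flags.append(
                    QCFlag(
                        flag_kind="replicate_spread",
                        scope="well",
                        detail=f"growth {row['growth']:.3f} deviates from condition median",
                        plate_id=row["plate_id"],
                        well=row["well"],
                        condition_id=str(cid),
                    )
                )
    return flags


# ---------------------------------------------------------- contamination

def detect_contamination(
    wells: pd.DataFrame,
    strict_auxotrophs: set[str],
    blank_margin: float = 0.05,
) -> list[QCFlag]:
    """Flag wells that grew where nothing should grow.

    (a) blank wells whose corrected growth exceeds ``blank_margin``;
    (b) monoculture wells of strict auxotrophs exceeding the margin while
    their condition median does not; (c) any non-blank well exceeding the
    margin while its condition's lower quartile stays at blank level —
    the condition as a whole shows no growth, so an individual grown well
    indicates contamination rather than biology (genuine syntrophy lifts
    all replicates). Wells 8-connected to a flagged well on the same
    plate inherit a soft warning.
    """
    flags: list[QCFlag] = []
    flagged_pos: list[tuple[str, int, int]] = []
    flagged_keys: set[tuple[str, str]] = set()

    def _flag(row, detail: str) -> None:
        key = (row["plate_id"], row["well"])
        if key in flagged_keys:
            return
        flagged_keys.add(key)
        flags.append(
            QCFlag(
                flag_kind="contamination",
                scope="well",
                detail=detail,
                plate_id=row["plate_id"],
                well=row["well"],
                condition_id=row["condition_id"],
            )
        )
        flagged_pos.append((row["plate_id"], int(row["row"]), int(row["col"])))

    for _, row in wells[wells["kind"] == "blank"].iterrows():
        if row["growth"] > blank_margin:
            _flag(row, f"blank grew to {row['growth']:.3f}")

    non_blank = wells[wells["kind"] != "blank"]
    med = non_blank.groupby("condition_id")["growth"].median()
    q25 = non_blank.groupby("condition_id")["growth"].quantile(0.25)
    for _, row in non_blank.iterrows():
        if row["growth"] <= blank_margin:
            continue
        cid = row["condition_id"]
        if (
            row["kind"] == "monoculture"
            and row["strain_1"] in strict_auxotrophs
            and med[cid] <= blank_margin
        ):
            _flag(
                row,
                f"strict auxotroph {row['strain_1']} grew to "
                f"{row['growth']:.3f} while condition median did not",
            )
        elif q25[cid] <= blank_margin:
            _flag(
                row,
                f"grew to {row['growth']:.3f} while condition lower quartile "
                "stayed at blank level",
            )

    if flagged_pos:
        pos_index = {
            (r["plate_id"], int(r["row"]), int(r["col"])): r
            for _, r in wells.iterrows()
        }
        seen = {(p, rr, cc) for p, rr, cc in flagged_pos}
        for plate, rr, cc in flagged_pos:
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    key = (plate, rr + dr, cc + dc)
                    if key in pos_index and key not in seen:
                        seen.add(key)
                        nb = pos_index[key]
                        flags.append(
                            QCFlag(
                                flag_kind="contamination",
                                scope="well",
                                detail="neighbour of contaminated well",
                                plate_id=nb["plate_id"],
                                well=nb["well"],
                                condition_id=nb["condition_id"],
                                hard=False,
                            )
                        )
    return flags


# -------------------------------------------------------- positional bias

def median_polish(
    matrix: np.ndarray, n_iter: int = 10, tol: float = 1e-9
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Additive decomposition value = overall + row + col + residual.

    Classic alternating median sweeps (Tukey); NaNs are ignored.
    Returns (overall, row_effects, col_effects, residuals).
    """
    import warnings

    resid = np.array(matrix, dtype=float)
    n_r, n_c = resid.shape
    overall = 0.0
    row_eff = np.zeros(n_r)
    col_eff = np.zeros(n_c)
    with warnings.catch_warnings():
        # all-NaN rows/columns (unused plate regions) legitimately yield NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        for _ in range(n_iter):
            rm = np.nanmedian(resid, axis=1)
            rm = np.where(np.isnan(rm), 0.0, rm)
            resid -= rm[:, None]
            row_eff += rm
            cm_r = np.nanmedian(row_eff)
            row_eff -= cm_r
            overall += cm_r

            cm = np.nanmedian(resid, axis=0)
            cm = np.where(np.isnan(cm), 0.0, cm)
            resid -= cm[None, :]
            col_eff += cm
            cm_c = np.nanmedian(col_eff)
            col_eff -= cm_c
            overall += cm_c
            if max(np.max(np.abs(rm)), np.max(np.abs(cm))) < tol:
                break
    return overall, row_eff, col_eff, resid


def positional_bias_flags(
    wells: pd.DataFrame, edge_bias_k: float = 3.0, mad_scale: float = 1.4826,
    mad_floor: float = 0.05, center_by_condition: bool = True,
) -> list[QCFlag]:
    """Detect plate positional artifacts on blank-corrected growth.

    Both tests run on condition-centred growth (each well minus its
    condition's median across the dataset) so that real growth
    differences between conditions are not mistaken for position; a
    positional artifact hits a well regardless of what grows in it and
    survives the centring. Two tests per plate, either of which flags:

    (a) edge effect — if |median(edge) - median(interior)| exceeds
        k * scaled-MAD(interior), every edge well on the plate is flagged;
    (b) row/column trend — additive row+column effects by median polish;
        wells whose fitted positional effect magnitude exceeds
        k * scaled-MAD(residuals) are flagged.

    Robust-MAD thresholds are floored at ``mad_floor`` so plates whose
    spread collapses to ~0 (most wells at zero growth) do not flag
    everything. Plates with a single condition carry no contrast and only
    get a soft warning.
    """
    flags: list[QCFlag] = []
    wells = wells.copy()
    if center_by_condition:
        cond_med = wells.groupby("condition_id")["growth"].transform("median")
        wells["growth"] = wells["growth"] - cond_med
    for plate, grp in wells.groupby("plate_id"):
        non_blank = grp[grp["kind"] != "blank"]
        if non_blank["condition_id"].nunique() < 2:
            flags.append(
                QCFlag(
                    flag_kind="positional_bias",
                    scope="assay",
                    detail="single-condition plate; no positional contrast",
                    plate_id=str(plate),
                    hard=False,
                )
            )
            continue
        fmt = 96 if grp["row"].max() < 8 and grp["col"].max() < 12 else 384

        edge_mask = grp.apply(lambda r: is_edge(int(r["row"]), int(r["col"]), fmt), axis=1)
        edge_vals = grp.loc[edge_mask, "growth"].to_numpy()
        int_vals = grp.loc[~edge_mask, "growth"].to_numpy()
        if edge_vals.size and int_vals.size:
            thr = edge_bias_k * max(scaled_mad(int_vals, mad_scale), mad_floor)
            if abs(np.median(edge_vals) - np.median(int_vals)) > thr:
                for _, row in grp[edge_mask].iterrows():
                    flags.append(
                        QCFlag(
                            flag_kind="positional_bias",
                            scope="well",
                            detail="edge effect",
                            plate_id=str(plate),
                            well=row["well"],
                            condition_id=row["condition_id"],
                        )
                    )

        shape = {96: (8, 12), 384: (16, 24)}[fmt]
        mat = np.full(shape, np.nan)
        for _, row in grp.iterrows():
            mat[int(row["row"]), int(row["col"])] = row["growth"]
        _, row_eff, col_eff, resid = median_polish(mat)
        thr = edge_bias_k * max(
            scaled_mad(resid[~np.isnan(resid)], mad_scale), mad_floor
        )
        effect = row_eff[:, None] + col_eff[None, :]
        for _, row in grp.iterrows():
            r_i, c_i = int(row["row"]), int(row["col"])
            if abs(effect[r_i, c_i]) > thr:
                flags.append(
                    QCFlag(
                        flag_kind="positional_bias",
                        scope="well",
                        detail=f"row/column trend effect {effect[r_i, c_i]:+.3f}",
                        plate_id=str(plate),
                        well=row["well"],
                        condition_id=row["condition_id"],
                    )
                )
    return flags


# --------------------------------------------------------------- Z-factor

def z_factor(pos, neg) -> float:
    """Screening-window statistic Z = 1 - 3(sd_pos + sd_neg)/|mean_pos - mean_neg|.

    Sample standard deviations. If the group means coincide the window is
    undefined and -inf is returned as a sentinel. Z <= 1 always; raises if
    either group has fewer than 2 values.
    """
    p = np.asarray(pos, dtype=float)
    n = np.asarray(neg, dtype=float)
    if p.size < 2 or n.size < 2:
        raise ValueError("z_factor requires >= 2 values per group")
    denom = abs(p.mean() - n.mean())
    if denom == 0:
        return -math.inf
    return float(1.0 - 3.0 * (p.std(ddof=1) + n.std(ddof=1)) / denom)


def activity_range_filter(
    coculture, fittest_mono, z_threshold: float = 0.5
) -> tuple[bool, str | None]:
    """Keep an assay only if its screening window is adequate.

    Positive group = coculture replicates, negative group = fittest
    constituent monoculture replicates. Drop when Z < ``z_threshold``.
    Returns (keep, reason-if-dropped).
    """
    co = np.asarray(coculture, dtype=float)
    mono = np.asarray(fittest_mono, dtype=float)
    if co.size < 2 or mono.size < 2:
        return False, "insufficient replicates"
    z = z_factor(co, mono)
    if z < z_threshold:
        return False, f"inadequate activity range (Z={z:.3f})"
    return True, None


# ------------------------------------------------------------ full cascade

def infer_strict_auxotrophs(
    wells: pd.DataFrame, blank_margin: float
) -> set[str]:
    """Strains whose monoculture median growth stays at blank level."""
    mono = wells[wells["kind"] == "monoculture"]
    med = mono.groupby("strain_1")["growth"].median()
    return set(med.index[med <= blank_margin])


def run_qc(tidy: pd.DataFrame, config: Config) -> QCResult:
    """Run the full well-level QC cascade on a tidy endpoint table.

    Returns growth values for every well, the flag list, and the subset
    of wells surviving hard well-level flags. Assay-level gates (bias
    inheritance, activity range) are applied during pair assembly.
    """
    wells, flags = blank_correct(tidy, config)
    flags += replicate_spread_flags(wells, config)
    strict = infer_strict_auxotrophs(wells, config.blank_margin)
    flags += detect_contamination(wells, strict, config.blank_margin)
    bias_flags = positional_bias_flags(
        wells, config.edge_bias_k, config.mad_scale, config.blank_margin
    )
    flags += bias_flags

    hard = {
        (f.plate_id, f.well)
        for f in flags
        if f.scope == "well" and f.hard
    }
    keep_mask = ~wells.apply(
        lambda r: (r["plate_id"], r["well"]) in hard, axis=1
    )
    kept = wells[keep_mask].reset_index(drop=True)

    # assay-level: any coculture replicate carrying a positional-bias flag
    # drops the whole assay
    bias_wells = {
        (f.plate_id, f.well) for f in bias_flags if f.scope == "well" and f.hard
    }
    co = wells[wells["kind"] == "coculture"]
    bias_dropped = {
        str(r["condition_id"])
        for _, r in co.iterrows()
        if (r["plate_id"], r["well"]) in bias_wells
    }

    logger.info(
        "QC: %d wells, %d hard well flags, %d assays bias-dropped",
        len(wells), len(hard), len(bias_dropped),
    )
    return QCResult(
        wells=wells,
        kept=kept,
        flags=flags,
        strict_auxotrophs=strict,
        bias_dropped_conditions=bias_dropped,
    )


def flags_table(flags: list[QCFlag]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "plate_id": f.plate_id,
                "well": f.well,
                "condition_id": f.condition_id,
                "flag_kind": f.flag_kind,
                "scope": f.scope,
                "hard": f.hard,
                "detail": f.detail,
            }
            for f in flags
        ],
        columns=["plate_id", "well", "condition_id", "flag_kind", "scope", "hard", "detail"],
    )
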