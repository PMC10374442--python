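"""Hit calling for pairwise coculture screens.

A coculture is a *hit* when it grows significantly better than its
fittest constituent monoculture: fold difference >= 1.5 and
Benjamini-Hochberg adjusted two-sided Welch p < 0.05 (defaults). A
``near_hit`` reporting tier captures assays with a passing fold
difference whose adjusted p lies in [alpha, 2*alpha); near hits are
never counted as hits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .plate_model import Condition, Config, StrainRecord
from .qc import ConditionSummary, QCResult, summarize, z_factor

logger = logging.getLogger(__name__)

P_CLAMP = 1e-300  # floor applied before taking logs for volcano export


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float
    degenerate: bool


def welch_test(group1, group2) -> WelchResult:
    """Two-sided Welch's t-test with Welch-Satterthwaite df.

    Degenerate conventions for replicates identical to instrument
    precision: both variances zero with differing means -> t = +-inf,
    p = 0; both zero with equal means -> t = 0, p = 1 (flagged).
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_test requires >= 2 values per group")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("welch_test requires finite values")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        if x.mean() == y.mean():
            return WelchResult(0.0, float(x.size + y.size - 2), 1.0, True)
        sign = 1.0 if x.mean() > y.mean() else -1.0
        return WelchResult(sign * math.inf, float(x.size + y.size - 2), 0.0, True)
    res = stats.ttest_ind(x, y, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue), False)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fittest_monoculture(
    mono_a: ConditionSummary, mono_b: ConditionSummary
) -> str:
    """The constituent monoculture with larger mean growth.

    Exact ties break lexicographically on condition_id (deterministic).
    """
    if mono_a is None or mono_b is None:
        raise ValueError("both monoculture summaries are required")
    if mono_a.mean_od > mono_b.mean_od:
        return mono_a.condition_id
    if mono_b.mean_od > mono_a.mean_od:
        return mono_b.condition_id
    return min(mono_a.condition_id, mono_b.condition_id)


def fold_difference(
    coculture: ConditionSummary, fittest: ConditionSummary, fd_floor: float = 1e-3
) -> tuple[float, bool]:
    """mean(coculture growth) / mean(fittest monoculture growth).

    Denominators below ``fd_floor`` are floored (flagged) so that
    non-growing monocultures produce large finite ratios rather than
    infinities. A non-positive coculture mean likewise yields the floored
    ratio fd_floor/denominator with a flag.
    """
    denom = max(fittest.mean_od, fd_floor)
    floored = fittest.mean_od < fd_floor
    numer = coculture.mean_od
    if numer <= 0:
        return fd_floor / denom, True
    return numer / denom, floored


@dataclass
class PairAssay:
    """One coculture with its two constituent monocultures and statistics."""

    coculture_id: str
    mono_ids: tuple[str, str]
    fittest_mono_id: str = ""
    summary_co: ConditionSummary | None = None
    summary_mono_a: ConditionSummary | None = None
    summary_mono_b: ConditionSummary | None = None
    z: float = math.nan
    fold_difference: float = math.nan
    t_stat: float = math.nan
    df: float = math.nan
    p_raw: float = math.nan
    p_adj: float = math.nan
    call: str = "dropped"
    drop_reason: str = ""
    degenerate: bool = False
    fd_floored: bool = False


def build_pair_assays(
    qc: QCResult, conditions: Sequence[Condition], config: Config
) -> list[PairAssay]:
    """Assemble per-coculture assays from QC-passed wells.

    Assays are dropped (with reason) when replicates are insufficient,
    when any coculture replicate carried a positional-bias flag, or when
    the Z-factor against the fittest monoculture falls below the
    activity-range threshold. Welch p-values are computed coculture vs
    fittest monoculture and BH-adjusted jointly across all surviving
    assays.
    """
    cond_by_id = {c.condition_id: c for c in conditions}
    mono_of_strain = {
        c.strains[0]: c.condition_id
        for c in conditions
        if c.kind == "monoculture"
    }
    growth = {
        cid: grp["growth"].to_numpy()
        for cid, grp in qc.kept.groupby("condition_id")
    }

    assays: list[PairAssay] = []
    for cond in conditions:
        if cond.kind != "coculture":
            continue
        s_a, s_b = cond.strains
        mono_a_id = mono_of_strain.get(s_a)
        mono_b_id = mono_of_strain.get(s_b)
        assay = PairAssay(
            coculture_id=cond.condition_id,
            mono_ids=(mono_a_id or "", mono_b_id or ""),
        )
        assays.append(assay)

        if cond.condition_id in qc.bias_dropped_conditions:
            assay.drop_reason = "positional bias"
            continue
        if mono_a_id is None or mono_b_id is None:
            assay.drop_reason = "missing monoculture condition"
            continue
        co_vals = growth.get(cond.condition_id, np.empty(0))
        a_vals = growth.get(mono_a_id, np.empty(0))
        b_vals = growth.get(mono_b_id, np.empty(0))
        if co_vals.size < 2 or a_vals.size < 2 or b_vals.size < 2:
            assay.drop_reason = "insufficient replicates"
            continue

        assay.summary_co = summarize(co_vals, cond.condition_id, config.mad_scale)
        assay.summary_mono_a = summarize(a_vals, mono_a_id, config.mad_scale)
        assay.summary_mono_b = summarize(b_vals, mono_b_id, config.mad_scale)
        assay.fittest_mono_id = fittest_monoculture(
            assay.summary_mono_a, assay.summary_mono_b
        )
        fittest_vals = a_vals if assay.fittest_mono_id == mono_a_id else b_vals
        fittest_sum = (
            assay.summary_mono_a
            if assay.fittest_mono_id == mono_a_id
            else assay.summary_mono_b
        )

        assay.z = z_factor(co_vals, fittest_vals)
        if assay.z < config.z_threshold:
            assay.drop_reason = f"inadequate activity range (Z={assay.z:.3f})"
            continue

        assay.fold_difference, assay.fd_floored = fold_difference(
            assay.summary_co, fittest_sum, config.fd_floor
        )
        w = welch_test(co_vals, fittest_vals)
        assay.t_stat, assay.df, assay.p_raw = w.t, w.df, w.p
        assay.degenerate = w.degenerate
        assay.call = "pending"

    tested = [a for a in assays if a.call == "pending"]
    if tested:
        adj = bh_adjust([a.p_raw for a in tested])
        for a, p in zip(tested, adj):
            a.p_adj = float(p)
    return assays


def call_hits(assays: list[PairAssay], config: Config) -> tuple[pd.DataFrame, dict]:
    """Apply the hit thresholds and build the annotated hit table.

    hit: p_adj < alpha and fold_difference >= fc_threshold.
    near_hit: fold gate passes, alpha <= p_adj < 2*alpha (reporting only).
    Returns (table, summary) where summary counts tested assays, hits and
    distinct deleted genes among hit constituents.
    """
    if not assays:
        raise ValueError("no assays to call")
    rows = []
    for a in assays:
        if a.call == "pending" or a.call in ("hit", "near_hit", "no_growth_advantage"):
            if a.p_adj < config.alpha and a.fold_difference >= config.fc_threshold:
                a.call = "hit"
            elif (
                a.fold_difference >= config.fc_threshold
                and config.alpha <= a.p_adj < 2 * config.alpha
            ):
                a.call = "near_hit"
            else:
                a.call = "no_growth_advantage"
        rows.append(
            {
                "coculture_id": a.coculture_id,
                "mono_a": a.mono_ids[0],
                "mono_b": a.mono_ids[1],
                "fittest_mono": a.fittest_mono_id,
                "mean_co": a.summary_co.mean_od if a.summary_co else math.nan,
                "mean_fittest": (
                    a.summary_mono_a.mean_od
                    if a.summary_co and a.fittest_mono_id == a.mono_ids[0]
                    else a.summary_mono_b.mean_od if a.summary_co else math.nan
                ),
                "z": a.z,
                "fold_difference": a.fold_difference,
                "t": a.t_stat,
                "df": a.df,
                "p_raw": a.p_raw,
                "p_adj": a.p_adj,
                "call": a.call,
                "drop_reason": a.drop_reason,
            }
        )
    table = pd.DataFrame(rows)

    hit_assays = [a for a in assays if a.call == "hit"]
    summary = {
        "n_cocultures_tested": sum(a.call != "dropped" for a in assays),
        "n_dropped": sum(a.call == "dropped" for a in assays),
        "n_hits": len(hit_assays),
        "n_near_hits": sum(a.call == "near_hit" for a in assays),
    }
    return table, summary


def unique_hit_genes(
    assays: list[PairAssay],
    conditions: Sequence[Condition],
    strains: Sequence[StrainRecord],
) -> set[str]:
    """Distinct deleted genes among the constituents of hit cocultures."""
    cond_by_id = {c.condition_id: c for c in conditions}
    gene_of = {s.strain_id: s.deleted_gene for s in strains}
    genes = set()
    for a in assays:
        if a.call != "hit":
            continue
        for sid in cond_by_id[a.coculture_id].strains:
            g = gene_of.get(sid, "")
            if g:
                genes.add(g)
    return genes


def volcano_table(assays: list[PairAssay]) -> pd.DataFrame:
    """Volcano-plot-ready export: log2 fold difference vs ln adjusted p.

    Adjusted p below 1e-300 is clamped before the log (flag column
    records clamping). Raw p is exported alongside since plotting either
    is defensible.
    """
    rows = []
    for a in assays:
        if a.call == "dropped" or math.isnan(a.p_adj):
            continue
        clamped = a.p_adj < P_CLAMP
        p = max(a.p_adj, P_CLAMP)
        rows.append(
            {
                "coculture_id": a.coculture_id,
                "log2_fc": math.log2(a.fold_difference),
                "ln_p_adj": math.log(p),
                "ln_p_raw": math.log(max(a.p_raw, P_CLAMP)),
                "call": a.call,
                "p_clamped": clamped,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["coculture_id", "log2_fc", "ln_p_adj", "ln_p_raw", "call", "p_clamped"],
    )
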