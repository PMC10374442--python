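"""Synthetic screen plates and coculture dynamics with known ground truth.

The endpoint-screen generator emulates the robotic workflow: every
non-blank well is seeded at 0.1 OD600-equivalents, read at 0 h and 48 h,
and carries multiplicative lognormal measurement noise. The null model
for cocultures encodes the observation that a leaky partner alone can
explain coculture growth: an unplanted pair grows to the *maximum* of
its constituents' leaky capacity, so only planted syntrophic pairs grow
beyond their fittest monoculture. Plate artifacts (edge offsets,
row/column gradients, sporadic contamination boosts) are planted with
recorded truth so the QC cascade can be scored.

The dynamics generator integrates a phenomenological two-species
obligate cross-feeding model (Monod uptake of the partner's exported
metabolite, shared logistic capacity) with fixed-step RK4, and renders
dual-channel fluorescence through known calibration slopes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_screen import TIDY_COLUMNS
from .plate_model import Condition, StrainRecord, is_edge, plate_shape, well_label


# ------------------------------------------------------------ screen part

@dataclass
class ScreenSimParams:
    """Study conditions for one simulated endpoint screen.

    Defaults emulate a small batch of the robotic screen: 16 library
    strains (a quarter of them leaky), all pairwise cocultures, 4
    replicates per condition on 384-well plates with 8 blanks each,
    5% multiplicative measurement noise and rare (p=0.005) contamination
    boosts of 0.2-0.8 OD.
    """

    n_strains: int = 16
    leaky_fraction: float = 0.25
    leakiness_range: tuple[float, float] = (0.05, 0.4)
    leakiness: dict[str, float] | None = None  # explicit override
    n_pairs: int | None = None  # subsample of all pairwise cocultures
    planted_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    carrying_od: float = 1.0
    noise_sd: float = 0.05
    edge_offset: float = 0.0
    row_slope: float = 0.0
    col_slope: float = 0.0
    biased_plates: list[str] | None = None  # None -> all plates when bias set
    contamination_prob: float = 0.005
    contamination_range: tuple[float, float] = (0.2, 0.8)
    replicates: int = 4
    plate_format: int = 384
    blanks_per_plate: int = 8
    inoculum_od: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.contamination_prob <= 1 and 0 <= self.leaky_fraction <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.carrying_od <= 0:
            raise ValueError("carrying_od must be > 0")


@dataclass
class SyntheticTruth:
    """Ground truth planted into a simulated screen."""

    planted_pairs: dict[str, float]          # coculture condition_id -> effect
    contaminated_wells: list[tuple[str, str]]  # (plate_id, well)
    biased_plates: list[str]
    leakiness: dict[str, float]
    dataset_id: str = ""


@dataclass
class SyntheticScreen:
    tidy: pd.DataFrame
    conditions: list[Condition]
    strains: list[StrainRecord]
    truth: SyntheticTruth
    params: ScreenSimParams


def _strain_ids(n: int) -> list[str]:
    return [f"S{i + 1:03d}" for i in range(n)]


def simulate_screen(params: ScreenSimParams) -> SyntheticScreen:
    """Generate a full screen batch with known truth.

    Biomass model at 48 h: monoculture of strain s grows to
    inoculum + leak_s * K; an unplanted coculture to
    inoculum + max(leak_a, leak_b) * K; a planted pair to
    inoculum + effect * K. Readings are biomass times lognormal noise;
    plate bias (edge offset plus centred row/column gradients) is added
    to the 48 h read only, and contamination boosts are added to sampled
    wells at 48 h. Blanks read small additive |N(0, 0.2*noise_sd)| noise.
    Output is byte-identical for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    sids = _strain_ids(params.n_strains)
    strains = [StrainRecord(strain_id=s, deleted_gene=f"gene_{s}") for s in sids]

    if params.leakiness is not None:
        leak = {s: float(params.leakiness.get(s, 0.0)) for s in sids}
    else:
        n_leaky = int(round(params.leaky_fraction * params.n_strains))
        leaky_ids = list(rng.choice(sids, size=n_leaky, replace=False))
        lo, hi = params.leakiness_range
        leak = {s: 0.0 for s in sids}
        for s in leaky_ids:
            leak[s] = float(rng.uniform(lo, hi))

    conditions: list[Condition] = [Condition("BLANK", "blank")]
    for s in sids:
        conditions.append(Condition(f"mono_{s}", "monoculture", (s,)))
    all_pairs = list(itertools.combinations(sids, 2))
    if params.n_pairs is not None and params.n_pairs < len(all_pairs):
        idx = rng.choice(len(all_pairs), size=params.n_pairs, replace=False)
        pairs = [all_pairs[i] for i in sorted(idx)]
    else:
        pairs = all_pairs
    pair_set = set(pairs)
    planted: dict[tuple[str, str], float] = {}
    for a, b, eff in params.planted_pairs:
        if a not in leak or b not in leak:
            raise ValueError(f"planted pair ({a}, {b}) references unknown strain")
        key = (a, b) if (a, b) in pair_set else (b, a)
        if key not in pair_set:
            pairs.append(key)
            pair_set.add(key)
        planted[key] = float(eff)
    for a, b in pairs:
        conditions.append(
            Condition(f"co_{a}__{b}", "coculture", (a, b), inoculation_ratio=(1.0, 1.0))
        )

    # layout: conditions are scattered randomly across plate positions so
    # that condition identity is not confounded with plate position
    # (randomized layouts are standard practice against positional bias)
    n_rows, n_cols = plate_shape(params.plate_format)
    wells_per_plate = n_rows * n_cols
    queue = [
        c for c in conditions if c.kind != "blank" for _ in range(params.replicates)
    ]
    per_plate = wells_per_plate - params.blanks_per_plate
    n_plates = math.ceil(len(queue) / per_plate)

    cond_by_id = {c.condition_id: c for c in conditions}
    biomass_48 = {}
    for c in conditions:
        if c.kind == "blank":
            biomass_48[c.condition_id] = 0.0
        elif c.kind == "monoculture":
            biomass_48[c.condition_id] = (
                params.inoculum_od + leak[c.strains[0]] * params.carrying_od
            )
        else:
            a, b = c.strains
            eff = planted.get((a, b), planted.get((b, a)))
            if eff is None:
                eff = max(leak[a], leak[b])
            biomass_48[c.condition_id] = params.inoculum_od + eff * params.carrying_od

    has_bias = params.edge_offset or params.row_slope or params.col_slope
    plate_ids = [f"P{p + 1:02d}" for p in range(n_plates)]
    if params.biased_plates is not None:
        biased = [p for p in params.biased_plates]
    else:
        biased = list(plate_ids) if has_bias else []

    records = []
    contaminated: list[tuple[str, str]] = []
    qi = 0
    for plate_id in plate_ids:
        order = rng.permutation(wells_per_plate)
        blank_slots = set(order[: params.blanks_per_plate].tolist())
        for w in order.tolist():
            r_i, c_i = divmod(w, n_cols)
            if w in blank_slots:
                cond = cond_by_id["BLANK"]
            else:
                if qi >= len(queue):
                    continue
                cond = queue[qi]
                qi += 1
            label = well_label(r_i, c_i, params.plate_format)

            if cond.kind == "blank":
                od0 = abs(rng.normal(0.0, 0.2 * params.noise_sd))
                od48 = abs(rng.normal(0.0, 0.2 * params.noise_sd))
            else:
                od0 = params.inoculum_od * math.exp(rng.normal(0.0, params.noise_sd))
                od48 = biomass_48[cond.condition_id] * math.exp(
                    rng.normal(0.0, params.noise_sd)
                )
            if plate_id in biased:
                bias = params.edge_offset * is_edge(r_i, c_i, params.plate_format)
                bias += params.row_slope * (r_i - (n_rows - 1) / 2)
                bias += params.col_slope * (c_i - (n_cols - 1) / 2)
                od48 += bias
            if rng.random() < params.contamination_prob:
                lo, hi = params.contamination_range
                od48 += rng.uniform(lo, hi)
                contaminated.append((plate_id, label))
            od48 = max(od48, 0.0)

            s1 = cond.strains[0] if len(cond.strains) > 0 else ""
            s2 = cond.strains[1] if len(cond.strains) > 1 else ""
            base = (plate_id, "batch1", label, r_i, c_i, cond.condition_id,
                    cond.kind, s1, s2)
            records.append(base + (0.0, od0))
            records.append(base + (48.0, od48))

    tidy = pd.DataFrame(records, columns=TIDY_COLUMNS)
    truth = SyntheticTruth(
        planted_pairs={f"co_{a}__{b}": e for (a, b), e in planted.items()},
        contaminated_wells=contaminated,
        biased_plates=biased,
        leakiness=leak,
        dataset_id=f"sim-seed{params.seed}",
    )
    return SyntheticScreen(tidy, conditions, strains, truth, params)


def validation_scenario(
    seed: int,
    n_strains: int = 64,
    n_planted: int = 50,
    leaky_fraction: float = 0.25,
    effect_range: tuple[float, float] = (0.3, 0.8),
    **overrides,
) -> ScreenSimParams:
    """Standard planted-screen conditions used for pipeline validation.

    The last quarter of the library is leaky (leakiness evenly spaced
    over 0.05-0.4); syntrophic pairs are planted among the *strict*
    strains only — planted syntrophy means growth beyond anything a
    constituent manages alone, which is only well-posed when the
    constituents do not grow by themselves. Effects are drawn uniformly
    from ``effect_range`` (in units of the carrying OD), far above the
    5% measurement noise. ``n_planted=0`` gives the matched null screen.
    """
    sids = _strain_ids(n_strains)
    n_leaky = int(round(leaky_fraction * n_strains))
    strict = sids[: n_strains - n_leaky]
    leak_values = np.linspace(0.05, 0.4, n_leaky) if n_leaky else []
    leakiness = {s: 0.0 for s in strict}
    leakiness |= {s: float(v) for s, v in zip(sids[len(strict):], leak_values)}

    rng = np.random.default_rng(seed)
    planted: list[tuple[str, str, float]] = []
    if n_planted:
        pairs = list(itertools.combinations(strict, 2))
        idx = rng.choice(len(pairs), size=n_planted, replace=False)
        lo, hi = effect_range
        planted = [
            (pairs[i][0], pairs[i][1], float(rng.uniform(lo, hi)))
            for i in sorted(idx)
        ]
    return ScreenSimParams(
        n_strains=n_strains,
        leakiness=leakiness,
        planted_pairs=planted,
        seed=seed,
        **overrides,
    )


def evaluate_calls(hit_table: pd.DataFrame, truth: SyntheticTruth) -> dict:
    """Confusion counts of hit calls against the planted syntrophic pairs.

    Precision is NaN when nothing was called. Dropped assays count as
    negative calls (a planted pair lost to QC is a miss).
    """
    called = set(hit_table.loc[hit_table["call"] == "hit", "coculture_id"])
    planted = set(truth.planted_pairs)
    tested = set(hit_table["coculture_id"])
    tp = len(called & planted)
    fp = len(called - planted)
    fn = len((planted & tested) - called)
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "precision": precision,
        "recall": recall,
        "n_called": len(called),
        "n_planted": len(planted),
    }


def evaluate_qc_flags(flags: pd.DataFrame, truth: SyntheticTruth) -> dict:
    """Score QC detection against planted contamination and plate bias."""
    hard_wells = set(
        zip(
            flags.loc[flags["hard"] & (flags["well"] != ""), "plate_id"],
            flags.loc[flags["hard"] & (flags["well"] != ""), "well"],
        )
    )
    contam = set(truth.contaminated_wells)
    detected = len(contam & hard_wells)
    bias_flags = flags[(flags["flag_kind"] == "positional_bias") & flags["hard"]]
    flagged_plates = set(bias_flags["plate_id"])
    return {
        "contamination_planted": len(contam),
        "contamination_detected": detected,
        "contamination_recall": detected / len(contam) if contam else float("nan"),
        "bias_plates_planted": len(truth.biased_plates),
        "bias_plates_detected": len(set(truth.biased_plates) & flagged_plates),
    }


# ---------------------------------------------------------- dynamics part

@dataclass
class CocultureSimParams:
    """Phenomenological obligate cross-feeding pair.

    Strain 1 (blue) grows only on metabolite E2 exported by strain 2 and
    vice versa (Monod uptake, half-saturation ``km``), both share one
    logistic carrying capacity ``carrying_od``. Export is proportional to
    exporter biomass (``rho``); the pool is drawn down in proportion to
    the consumer's growth (``yield_coeff`` OD-equivalents of metabolite
    per OD of growth). Rates are per hour; ODs in OD600 units.
    """

    r1: float = 0.4
    r2: float = 0.4
    carrying_od: float = 1.0
    rho1: float = 0.05
    rho2: float = 0.05
    km: float = 0.01
    yield_coeff: float = 0.5
    inoculum_total: float = 0.1
    fraction_blue: float = 0.5
    duration: float = 72.0
    step: float = 0.025
    record_every: float = 1.0 / 3.0  # 20-min reader interval
    slope_blue: float = 1200.0
    slope_red: float = 900.0
    background_blue: float = 50.0
    background_red: float = 40.0
    channel_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step <= 0 or self.duration <= 0:
            raise ValueError("step and duration must be > 0")
        if min(self.r1, self.r2, self.rho1, self.rho2) < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class CocultureRun:
    times: np.ndarray
    n_blue: np.ndarray
    n_red: np.ndarray
    f_blue: np.ndarray
    f_red: np.ndarray
    true_proportion_blue: np.ndarray
    params: CocultureSimParams


def _derivs(state: np.ndarray, p: CocultureSimParams) -> np.ndarray:
    n1, n2, e1, e2 = state
    cap = max(1.0 - (n1 + n2) / p.carrying_od, 0.0)
    g1 = p.r1 * n1 * (e2 / (p.km + e2)) * cap if e2 > 0 else 0.0
    g2 = p.r2 * n2 * (e1 / (p.km + e1)) * cap if e1 > 0 else 0.0
    de1 = p.rho1 * n1 - p.yield_coeff * g2
    de2 = p.rho2 * n2 - p.yield_coeff * g1
    return np.array([g1, g2, de1, de2])


def _integrate(
    state0: np.ndarray, p: CocultureSimParams
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step RK4 with nonnegativity clamp on metabolite pools."""
    n_steps = int(round(p.duration / p.step))
    record_stride = max(int(round(p.record_every / p.step)), 1)
    state = state0.astype(float).copy()
    times = [0.0]
    states = [state.copy()]
    for i in range(1, n_steps + 1):
        h = p.step
        k1 = _derivs(state, p)
        k2 = _derivs(state + 0.5 * h * k1, p)
        k3 = _derivs(state + 0.5 * h * k2, p)
        k4 = _derivs(state + h * k3, p)
        state = state + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        state[2:] = np.clip(state[2:], 0.0, None)
        if i % record_stride == 0 or i == n_steps:
            times.append(i * h)
            states.append(state.copy())
    return np.array(times), np.array(states)


def simulate_coculture_dynamics(params: CocultureSimParams) -> CocultureRun:
    """Integrate one batch culture and render fluorescence channels."""
    rng = np.random.default_rng(params.seed)
    n1_0 = params.inoculum_total * params.fraction_blue
    n2_0 = params.inoculum_total * (1.0 - params.fraction_blue)
    times, states = _integrate(np.array([n1_0, n2_0, 0.0, 0.0]), params)
    n1, n2 = states[:, 0], states[:, 1]
    total = n1 + n2
    prop = np.where(total > 0, n1 / np.where(total > 0, total, 1.0), np.nan)

    noise = lambda size: np.exp(rng.normal(0.0, params.channel_noise_sd, size)) \
        if params.channel_noise_sd > 0 else np.ones(size)
    fb = (params.slope_blue * n1) * noise(n1.size) + params.background_blue
    fr = (params.slope_red * n2) * noise(n2.size) + params.background_red
    return CocultureRun(times, n1, n2, fb, fr, prop, params)


def simulate_passages(
    params: CocultureSimParams, n_passages: int = 2
) -> list[CocultureRun]:
    """Serial batch passages: dilute to total OD 0.10, reset metabolite pools.

    Each passage re-seeds at the previous passage's final composition,
    rescaled to the standard total inoculum; metabolite pools start empty
    again (fresh medium).
    """
    import dataclasses as _dc

    runs = []
    p = params
    for i in range(n_passages):
        run = simulate_coculture_dynamics(p)
        runs.append(run)
        final_prop = run.true_proportion_blue[-1]
        p = _dc.replace(p, fraction_blue=float(final_prop), seed=p.seed + 1)
    return runs


def run_to_frame(run: CocultureRun) -> pd.DataFrame:
    """Trajectory CSV schema shared with the popdyn readers."""
    return pd.DataFrame(
        {
            "time": run.times,
            "F_blue": run.f_blue,
            "F_red": run.f_red,
            "true_od_blue": run.n_blue,
            "true_od_red": run.n_red,
            "true_proportion_blue": run.true_proportion_blue,
        }
    )
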