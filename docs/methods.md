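# Methods

## The assay being modelled

A pairwise growth-complementation screen co-inoculates two auxotrophic
yeast deletion mutants at a 1:1 ratio (total inoculum 0.1
OD600-equivalents) in synthetic minimal medium on 384-well plates,
alongside each constituent monoculture and blank wells. OD600 is read
at 0 h and 48 h. A coculture that grows substantially better than its
fittest constituent monoculture is evidence of spontaneous metabolic
cross-feeding (syntrophy): neither strain can make the missing
metabolite itself, so community growth implies exchange.

The statistical problem has three adversaries: *leaky* auxotrophs that
grow alone by 48 h and erase the assay window; plate artifacts
(edge-seal handling, row/column gradients, sporadic cross-well
contamination); and multiple testing across thousands of pairs.

## Growth metric and blank correction

Growth is the endpoint change `g = OD(48) − OD(0)` minus the median
blank change on the same plate, floored at 0. Subtracting the 0 h read
removes the inoculum; the plate-wise blank median removes media/optics
background. The floor keeps downstream ratios well defined; raw deltas
are retained in every output so nothing is lost. Plates without blanks
fall back to the raw delta and carry a soft warning. Flags gate
inclusion only — no value used for hit calling is ever adjusted beyond
this blank correction.

## QC cascade

**Replicate spread.** Replicate *i* of a condition is flagged when
`|g_i − med| > k·1.4826·MAD` with `k = 3`; 1.4826 makes the MAD
consistent with σ under normality. If the MAD collapses to zero
(robotically identical replicates), values further than `blank_margin`
(0.05 OD) from the median are flagged instead. Because the plain MAD
over four replicates has breakdown point one — two coincident outliers
mask each other — a leave-one-out variant additionally tests each
replicate against the median and MAD of the remaining three, with the
same threshold floored at `blank_margin`. Flagged wells are removed;
the assay continues with the remaining replicates.

**Contamination.** Three rules on blank-corrected growth, margin
`blank_margin = 0.05` OD: (a) a blank well that grew; (b) a
strict-auxotroph monoculture well that grew while its condition median
did not; (c) any non-blank well that grew while its condition's lower
quartile stayed at blank level — genuine syntrophy lifts all
replicates, so an isolated grown well in a no-growth condition is a
contamination event, and the lower quartile tolerates up to two
contaminated wells out of four. Strictness is inferred from the data
(monoculture median growth ≤ `blank_margin`). Wells 8-connected to a
contaminated well get a soft (non-gating) warning. A separate
`classify_auxotroph` helper implements the preselection rule used to
build such libraries — SM growth strictly below 20% of the prototrophic
parent while retaining ≥ 50% of parent growth on complete medium; the
50% figure is this package's own configurable choice.

**Positional bias.** Both tests run per plate on *condition-centred*
growth (each well minus its condition's median across the dataset).
Centring is essential: growth differences between conditions laid out
non-uniformly would otherwise masquerade as positional structure, while
a true positional artifact hits wells regardless of content and
survives the subtraction. Test (a): if the edge-well median differs
from the interior median by more than `k·scaledMAD(interior)`
(`k = 3`), every edge well is flagged and any assay with a coculture
replicate on that plate's edge is dropped. Test (b): additive
row+column effects are fitted by Tukey median polish (alternating
median sweeps, 10 iterations, NaN-tolerant) and wells whose fitted
positional effect exceeds `k·scaledMAD(residuals)` are flagged. Both
MAD thresholds are floored at `blank_margin` so a plate whose residual
spread collapses (most wells at zero growth) does not flag everything.

**Activity range.** The screening-window statistic
`Z = 1 − 3(σ_pos + σ_neg)/|µ_pos − µ_neg|` (sample SDs) is computed
with the coculture as positive group and the fittest constituent
monoculture as negative group; assays with `Z < 0.5` are dropped. The
0.5 cut is the conventional "excellent assay" threshold from the
screening literature and is configurable. Equal group means return a
−∞ sentinel (always dropped). This is the gate that removes leaky-
auxotroph assays: the fraction of assays dropped rises monotonically
with the leakiness of the fittest constituent.

## Hit calling

Per assay: fold difference `FC = µ_co / max(µ_fittest, fd_floor)`
(`fd_floor = 1e−3` OD keeps non-growing denominators finite and is
flagged when active; ties in the fittest-monoculture choice break
lexicographically for determinism) and a two-sided Welch *t*-test of
coculture vs fittest-monoculture replicates with Welch–Satterthwaite
degrees of freedom. Zero-variance conventions for instrument-identical
replicates: both variances zero with distinct means → `t = ±∞, p = 0`;
with equal means → `t = 0, p = 1`; both flagged degenerate.
Benjamini–Hochberg correction is applied once across all QC-surviving
cocultures (one family per run). Calls: **hit** iff `p_adj < α = 0.05`
and `FC ≥ 1.5`; **near_hit** (reporting tier only, never counted as a
hit) when the fold gate passes and `α ≤ p_adj < 2α`. The volcano
export clamps `p_adj` at 1e−300 before taking logs and flags clamped
rows; both adjusted and raw log-p columns are exported since either is
a defensible y-axis.

Welch's test is evaluated through `scipy.stats.ttest_ind(equal_var=False)`
and BH through `statsmodels.multipletests`; the test suite checks both
against independent oracles (exact rational-arithmetic evaluation of the
Welch formulas; a hand-coded step-up over all permutations of up to six
p-values) to 1e−10 relative.

## Synthetic screen generator

The generator emulates the robotic workflow so the whole pipeline runs
on data with known truth. Biomass model at 48 h: monoculture of strain
*s* reaches `0.1 + leak_s·K`; an unplanted coculture reaches
`0.1 + max(leak_a, leak_b)·K` — encoding that, absent syntrophy, a
coculture grows exactly as well as its leakier member; a planted
syntrophic pair reaches `0.1 + effect·K`. Defaults, chosen once as a
realistic small batch and not revisited: carrying capacity `K = 1.0`
OD, 5% multiplicative lognormal measurement noise, 4 replicates per
condition, 384-well plates with 8 blanks each, contamination
probability 0.005 per well with a uniform(0.2, 0.8) OD boost.
Conditions are scattered over plate positions by a seeded random
permutation — the standard defence against confounding condition with
position. Plate bias (edge offset, centred row/column gradients) is
added to the 48 h read only, mimicking artifacts introduced by seal
handling between reads; blanks receive small additive `|N(0,
0.2·noise_sd)|` noise because multiplicative noise on a zero signal is
degenerate. All randomness flows from one `numpy` generator seed;
fixed seed ⇒ identical output.

The standard validation scenario (`validation_scenario`) uses 64
strains (2,016 pairwise cocultures, the same order of magnitude as the
screens this mirrors), the last quarter leaky with leakiness evenly
spaced over 0.05–0.4, and 50 planted pairs (≈2.5% of pairs, matching
observed hit rates) with effects uniform in 0.3–0.8·K. Pairs are
planted among *strict* strains only: planted syntrophy means growth
beyond anything a constituent manages alone, which is only well posed
when the constituents do not grow by themselves — pairs whose planted
effect falls below a partner's own leakiness have no detectable window
and would be (correctly) removed by the activity-range gate.

## Coculture dynamics model

A deliberately phenomenological obligate cross-feeding pair: strain
*i* grows only on the metabolite pool exported by its partner,

    dN1/dt = r1·N1·(E2/(Km+E2))·(1 − (N1+N2)/K)
    dE1/dt = ρ1·N1 − y·dN2/dt        (pools clipped at 0)

and symmetrically for strain 2. Monod uptake (`Km = 0.01` OD-equiv)
gives the characteristic inoculation-ratio-dependent lag; the shared
logistic capacity couples the strains' fates; export `ρ` proportional
to exporter biomass and consumption proportional to consumer growth
(`y = 0.5`) close the loop. No metabolite identity is claimed — the
model targets the qualitative repertoire (ratio-dependent lag,
convergence to a characteristic composition, re-establishment after
passage), not any measured curve. Integration is fixed-step RK4
(default step 0.025 h, recorded every 20 min over 72 h): deterministic,
dependency-light, and adequate for smooth logistic dynamics — halving
the step changes trajectories by < 1e−4 relative at default rates.
Serial passages rescale the final composition to total OD 0.10 and
reset the metabolite pools (fresh medium).

Fluorescence channels are rendered as `F = slope·N + background` with
optional multiplicative channel noise, using blue (BFP-like,
ex400/em465) and red (mScarlet-like, ex560/em620) slopes of 1200 and
900 units/OD — arbitrary but realistic magnitudes.

## Unmixing and stability

Calibration lines are ordinary least squares on monoculture dilution
series (the workflow's standard dilution ODs 0.95…0.05). Unmixing
solves the 2×2 system `A·od = F − background` by least squares; the
mixing model is linear with additive background and optional crosstalk
slopes (default 0 — the two channels are spectrally well separated).
Negative components are clipped to 0 and logged; a singular slope
matrix (condition number > 1e12) is an error. The proportion is
defined only where `od_blue + od_red > 0`. Total OD is carried but not
used to constrain the solution by default, since the linear system is
already determined.

Passage stability: `final_delta = |p_end(pass 1) − p_end(pass 2)|`,
with trajectories compared by Pearson correlation on the union grid of
relative times (linear interpolation, ≥ 3 common points). A
composition is called *re-established* when `final_delta ≤ 0.15` — an
invented, clearly configurable tolerance for a qualitative judgement.

## Problem sizes and what the tests show

Validation runs use 2,016-pair screens (~8,500 wells) and 72 h
trajectories at 20-min resolution; these sizes give stable Monte-Carlo
estimates while keeping the full suite fast. Passing tests show that
the pipeline controls false positives under the generator's null,
recovers planted effects ≥ 3× measurement noise with ≥ 0.9 recall and
precision, and detects the planted artifact classes — on data matching
the generator's assumptions (lognormal noise, additive bias, max-leak
null). Real screens add unmodelled structure (batch effects between
robot rounds, growth-curve shape differences, biological replicate
correlation), so thresholds here are defaults to be reviewed per
dataset, not guarantees.

## Known limitations

* The positional-bias mechanism (edge contrast + median polish) is one
  reasonable concretization of plate-artifact detection; alternative
  detectors can be plugged in behind the same flag interface.
* Whether the activity-range gate should use the fittest monoculture or
  both monocultures as the negative group is a judgement call; this
  implementation uses the fittest (the binding constraint), and the
  choice is isolated in one function.
* Hit calling uses plain Welch tests; no variance moderation or
  effect-size shrinkage across the screen is attempted.
* Contamination detection cannot distinguish three-or-four-fold
  contamination of a single condition from genuine growth; its
  guarantees degrade past two events per condition.
* The dynamics model is not mechanistic: rates are per-hour
  phenomenological constants, not measured exchange kinetics.
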