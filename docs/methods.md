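# Methods

This note documents the model implemented by `damsim`, the choices made where
the design was genuinely open, and what the shipped tests do and do not show.

## Model

Two point-agents — an attacher (child) and a caregiver (mother) — interact in
a square lab with coordinates in `[1, S]`, `S = 30`. Iterations beat a
"psychological time": one step is one meaningful interaction event, not a
fixed physical interval. Each simulated session expresses exactly one
attachment dimension, avoidance or ambivalence; avoidance is an *emotional*
dimension (deactivation, induced by caregiver insensitivity `I_n`) and
ambivalence a *physical* one (hyper-activation, induced by caregiver
unresponsiveness `U_n`). The dyad is adapted: `A_v = I_n`, `A_m = U_n`,
fixed over the run.

Per iteration the update order is fixed and synchronous:

1. **Behavioral variables.** Distance `d` from current positions;
   indifference `i` = cumulative % of past iterations in which the caregiver
   chose to explore.
2. **Perceptions.** `S_E` (avoidance) or `D_P` (ambivalence) for each agent:
   `P[n] = P[n−1] + 2r·[(obs[n] − T_obs) − (P[n−1] − T_P)]`, `r ~ U[0,1]`.
   The noisy step has mean one, so in expectation the perception relaxes onto
   `T_P + (obs − T_obs)`.
3. **Drives.** Each agent's drive from the care clock `K`, the *other*
   agent's need of the previous iteration, and the fresh perception divided
   by `percept_scale` (see below), plus a constant offset.
4. **Needs.** `N(x, h) = x/(x + h^x)`.
5. **Thresholds.** `T = T_bl ± τ(1 + r)`: minus while the agent's own need is
   strictly decreasing (a deactivating system re-arms readily), plus
   otherwise; the first iteration, with need unchanged from its initial
   value, takes the plus sign.
6. **Care clock.** Care counts as provided when the caregiver's need exceeds
   its threshold; then `K → 0`, else `K → K + 1`. No spatial proximity is
   required (a proximity-gated variant is config-exposed).
7. **Action selection.** Explore when `N < T` *and* the controlled perception
   sits below `k·target`; approach when `N > T` *and* it sits above. The two
   remaining quadrants are motivational conflicts, resolved to exploration
   and flagged (see below).
8. **Movement.** Simultaneous, from start-of-iteration positions. Approach
   heads for the other agent; exploration heads for the nearest visible,
   non-refractory owned object, else moves full speed in a uniformly random
   direction. A target beyond the speed limit is approached exactly `speed`
   along the bearing; a reachable target is "arrived at" by landing uniformly
   within ±0.5 of it per coordinate. Reaching an object starts its 7-iteration
   refractory period. Positions clamp to the lab bounds.

## Hill parameters

The need function's parameter `h` controls steepness: smaller `h` means more
felt need per unit of drive. Each agent's `h` equals its own normalized
set-goal — avoidance: `h = A_v` for both agents (the same emotional goal);
ambivalence: `h = 1 − A_m` for the attacher and `h = U_n` for the caregiver
(opposite distance goals). This single rule makes the need curves express the
dimensions' defining asymmetry: rising avoidance flattens both agents' needs
(deactivation), rising ambivalence sharpens the child's need while flattening
the caregiver's (hyper-activation against withdrawal). The coupling terms use
the other agent's actual need of the previous iteration — each agent perceives
the other's real activation — so one `h` per agent is used consistently
everywhere.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `Cf_av`, `Cf_am` | 4, 2 | coupling weight of the other agent's need |
| `c0a_av`, `c0c_av` | 0.49, 0.50 | avoidant drive offsets |
| `c0a_am`, `c0c_am` | 0.20, 0.50 | ambivalent drive offsets |
| `T_bl`, `tau` | 0.75, 0.08 | threshold baseline and excursion |
| `k_E`, `k_P` | 1.01, 1.10 | action-rule margins on the perception |
| `K_coeff` | 0.5 | care-clock weight in the drives |
| `percept_scale` | 100 | divisor of S_E/D_P inside the drives |
| `S` | 30 | lab side (coordinates 1…S) |
| `L` | √2·S | reference length for speed/vision |
| speeds/visions | L/9, L/3 (child); L/3, L/1 (caregiver) | caregiver 3× the child |
| refractory | 7 | iterations an explored object is unattractive |
| `n_iterations` | 1000 | session length |

Initial conditions (identical in all runs): `K = 0`, needs 0.75, `S_E = D_P =
50`, `i = 55`, child at (9,15), caregiver at (21,15) (hence `d = 12`). These
are the control fixed point of the level-0.5 dyad, so every sweep starts from
the same neutral state.

## Design choices at open points

* **Perception scaling.** `S_E`/`D_P` live on a 0–100 scale while needs must
  oscillate near `T_bl = 0.75`; the drives divide perceptions by
  `percept_scale = 100`, which keeps drives of order one and produces
  threshold crossings as `K` grows by a few. Exposed in config.
* **Reference length `L`.** Taken as the lab diagonal `√2·S`, under which the
  caregiver's vision `L/1` covers the whole lab — it always sees its objects
  — and the child's vision `L/3 ≈ 14` covers roughly a third. `L = 2S` is one
  config flag away.
* **Conflict quadrants.** The selection rule is silent when need and
  perception disagree (e.g. need without felt separation). Such iterations
  fall back to exploration — the default motivational baseline when neither
  attachment nor caregiving is coherently triggered — and carry a flag in the
  record. Summary statistics keep approach / coherent-explore / conflict
  disjoint (they sum to 100%).
* **Indifference counts motivated exploration only.** The cumulative counter
  behind `i` tallies the caregiver's *coherent* explorations, not
  conflict-resolved fallback moves. This closes the control loop: `i` then
  stabilizes near its target `T_i = 1.1·T_E`, and with it the whole avoidant
  action pattern (child exploration rising from ~13% to ~94% across levels,
  approach falling from ~47% to 0). Counting fallback moves instead
  decouples `i` from `T_i` and collapses coherent exploration at low
  avoidance.
* **"Explored" trigger.** An object is consumed when an exploring agent ends
  the iteration within the ±0.5 arrival band of it; the refractory window is
  `[n+1, n+7]`, selectable again at `n+8`; re-marking keeps the later expiry.
* **Threshold hysteresis trigger.** "Need decreasing" is a strict decrease of
  the agent's own need between consecutive iterations.
* **Dimension activation** (softmax winner-take-all over the two levels with
  standard-normal contextual noise) is available (`activate_dimension`, CLI
  `activate`) but default runs fix the dimension explicitly.
* **RNG architecture.** One master seed spawns independent named streams
  (perception noise per agent, threshold noise per agent, movement jitter per
  agent, activation), so toggling one stochastic element never shifts the
  draws of another. Runs are bitwise reproducible from the config + seed; a
  run manifest re-executes byte-identically.

## Experiments

`sweep` runs the nine levels 0.1…0.9 of one dimension with the adapted-dyad
constraint, averaging each summary statistic over replicate seeds (default
10; the per-seed spread is reported). The published study reports single
1,000-iteration runs per level; replicate averaging is this package's choice
for stable trend statistics at negligible cost. `trend_check` tests each
statistic's monotone trend via Spearman rank correlation over the nine level
means, passing at the expected sign with |ρ| ≥ 0.8 (the source evidence is
visual monotonicity; the threshold is config-exposed). `sensitivity_coupling`
re-runs the sweep with the coupling factor zeroed; the coupled system should
pass at least as many trend checks. The variable-coefficient avoidant variant
(`variable_c0`) replaces the constant offsets with `c0a_av = −0.30·A_v + 0.60`
and `c0c_av = −0.30·A_v + 0.59`, widening the dynamic range of needs and
actions across levels. `smooth` is a centered moving average (default window
10) used only for presentation; all statistics use raw series.

## What the tests show — and don't

The synthetic dynamics are the object of study here, not a stand-in for data:
the model's claim is qualitative agreement between simulated trends and the
attachment literature's expectations. The test suite verifies (a) the exact
closed-form behavior of every equation against independent arithmetic
oracles, (b) that at study scale all 12 directional trends hold with
|ρ| ≥ 0.8, and (c) that the seed-averaged percentages land at the magnitudes
the model is known for (avoidant child need ≈57% at level 0.1 falling to ≈6%
at 0.9; exploration ≈13% → ≈94%; ambivalent caregiver need ≈74% at 0.1;
ambivalent child need ≈98% at 0.9). None of this demonstrates correspondence
with *measured* human dyads — the model has no physical embodiment, one
behavior per motivational system, and a qualitative evaluation standard.

## Numerical notes and limitations

* `need` attains 1.0 by floating-point rounding once `h^x` drops below the
  ULP of `x` (large drives at small `h`); harmless, as action selection only
  compares against thresholds < 1.
* `S_E` is clamped to [0, 100] and `D_P` to [0, 100·√2]; the perception
  recursions are otherwise unbounded.
* Ties in the action rule (`N = T` or perception exactly at the margin)
  resolve to the conflict branch; exact ties have measure zero under the
  continuous noise.
* The model covers two of the attachment dimensions; disorganization and
  phobicity, learning of the dimensional levels, multi-dimension co-activation
  and continuous-time dynamics are out of scope.
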