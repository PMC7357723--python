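# Methods

## Scope and assumptions

`ssnmrice` computes pre-season, field-specific fertilizer plans for
irrigated transplanted or direct-seeded rice, and evaluates populations of
such plans economically and in terms of soil P/K budgets. It assumes:

- one rice crop per recommendation, with establishment day counted as day 0
  ("days after establishment", DAE);
- nutrient outputs occur only through crop removal (no leaching, runoff or
  gaseous losses in the P/K budget), and organic inputs other than rice
  straw are excluded;
- irrigation water carries K but negligible P;
- zinc is a fixed basal line item (25 kg zinc sulfate ha⁻¹), not diagnosed
  per field;
- no in-season adjustment (no leaf-color-chart N top-ups, no weather or
  crop-model feedback).

## Target yield

`set_target_yield` implements: historical yield + seasonal increment,
clamped to the variety's baseline window, then a late-establishment penalty
where configured, with the result held within
[historical, historical + 2.5]. All five quantities (increment 1.0 Mg ha⁻¹,
maximum 2.5, window, cutoff, penalty) are `SeasonParams` fields, so a
locally derived target-yield table can be dropped in without code changes.
Only kuruvai ships a cutoff (15 June); samba and thaladi deliberately do
not, mirroring regional practice, though the same mechanism can be enabled
for them as the known candidate improvement for late-established second
crops. The penalty value of 0.5 Mg ha⁻¹ is a calibration choice: with mean
reported history of 4.8 Mg ha⁻¹, a +1.0 increment and the kuruvai window
[4.6, 6.1], it centers kuruvai targets near the observed 5.4 Mg ha⁻¹ for a
season in which every trial was transplanted after the cutoff.

## Rate equations and calibration

**N (yield gain).** FN = 1000 × (target − yield_without_N) / AE, rounded to
1 kg ha⁻¹. `yield_without_n` — the yield supported by indigenous N alone —
is rarely known directly at interview time, so it defaults to
target − `attainable_gain`, keeping the yield-gain equation intact while
letting a measured omission-plot value override it. Defaults: AE 15 kg
grain per kg N (the upper end of the 14–15 range in regional use);
attainable gains 1.8 (kuruvai) and 1.95 (samba, thaladi) Mg ha⁻¹, which
reproduce the regional field-specific N means of 120/130/130 kg ha⁻¹ at
the seasonal mean targets.

**P (full maintenance).** FP = target × effective P removal. Removal
coefficients: 1.8 kg P per Mg in grain plus 0.79 in straw (straw share
≈ 30% of plant P, the accepted partitioning for rice), totalling 2.59 kg P
Mg⁻¹ when straw is exported — which maps targets 5.4/5.8 onto rates 14/15
kg P ha⁻¹. When the previous crop's straw was retained, the straw term is
scaled by (1 − retention efficiency), retention defaulting to 0.8 for
combine-harvested residue.

**K (partial maintenance).** FK = removal − irrigation input − residue
input + targeted drawdown, floored at 0. Removal: 2.5 kg K per Mg in grain
plus 13.25 in straw (straw share 84%, within the 80–85% range for rice),
15.75 kg K Mg⁻¹ total. Irrigation K inputs 25/8/4 kg ha⁻¹ for
kuruvai/samba/thaladi follow from a mean 2.6 mg K L⁻¹ in tube-well water
and seasonal irrigation volumes; targeted drawdowns are −30/−33/−4
kg ha⁻¹. Residue K input = previous-crop yield × straw K coefficient ×
retention efficiency; the previous-crop yield defaults to the reported
historical yield when not stated. At target 5.4 this yields the kuruvai
rate 85 − 25 − 30 = 30 kg K ha⁻¹ exactly; the samba reconstruction
(≈ 50 kg ha⁻¹ at target 5.8) sits 2 kg below the published 52, a residual
attributable to per-field heterogeneity that printed season means cannot
recover.

The coefficients are parameters on `SeasonParams`, never literals inside
the rate functions, and the balance module consumes the same functions
(`p_removal`, `k_removal`) so the maintenance identities hold by
construction: at achieved = target, P balance = 0 and K balance = targeted
drawdown, to the ±0.5 kg ha⁻¹ quantization introduced by rounding rates to
whole kilograms.

## Scheduling

Panicle initiation is placed `duration_in_field − 65` DAE, where
duration_in_field subtracts the nursery period (seedling age) for
transplanted rice; the 65-day reproductive-plus-ripening offset and the
early-dose day (7, within the required ≤ 11) are module constants exposed
as function arguments. Active tillering sits midway between the early dose
and PI, rounded down. N splits 24/38/38 when PI ≥ 30 DAE and into equal
thirds when PI < 30 (strict); with a 110-day variety and 25-day seedlings
PI lands at DAE 20, so short-duration kuruvai crops take the equal-split
branch. All P and an early K fraction (default 0.55 of a practiced
0.50–0.58 window) join the early dose, the remaining K goes out at PI.
Doses are rounded to 0.5 kg with largest-remainder repair so every
schedule conserves its totals bit-exactly. The blanket reference schedule
is fixed: 150/22/42 kg N/P/K ha⁻¹ with N and K in four equal splits and
all P basal.

## Product allocation

Fixed source roles, not least-cost blending: the first P-bearing product in
the farmer's stated preference order satisfies P exactly (its N and K
contributions are credited), the farmer's straight-K source (else muriate
of potash) fills early K, urea fills remaining early N and is never
negative — if co-products oversupply N the allocation warns rather than
fails. Later events use urea and muriate of potash only. Default elemental
grades derive from P = P₂O₅ × 0.436 and K = K₂O × 0.830 (urea 46% N; DAP
18% N / 20.1% P; MOP 49.8% K; SSP 7.0% P; 17-17-17 and 20-20-0
analogously), with catalog CSV override. Masses are rounded to 0.1 kg
internally and displayed to 0.5 kg.

## Economics

Total fertilizer cost = Σ(mass/50 × price per 50 kg) + applications × 9.5
US\$ ha⁻¹ labor; gross return uses the 222 US\$ Mg⁻¹ minimum support
price. PFP is undefined (raises) at FN = 0 rather than returning infinity.
Added net benefit is computed per field and then averaged, so its mean
equals the difference of mean gross returns over common fields (linearity,
tested). Exceedance probabilities count ties as exceeding (P(ANB ≥ t)),
making boundary thresholds deterministic; the loss probability is
P(ANB < 0). Summaries round to the dollar, and PFP and percentages to
integers, matching reporting precision.

## Synthetic populations

The fixtures module emulates a three-season on-farm trial series (14/40/20
fields): historical yields from truncated normals (means 4.8/4.8/4.4, sd
0.8/0.8/0.6, observed ranges), varietal windows equal to the observed
seasonal target ranges, calendars with kuruvai sowing 8–23 June (so every
kuruvai field incurs the late penalty) and 20–30-day nursery periods.
Truncated normals are drawn by rejection — exact and cheap at these sizes.
Plot yields follow
`min(target × attainment, yield_without_N + AE_realized × N/1000) + ε`,
ε ~ N(0, 0.15 Mg ha⁻¹): the first term is the weather/establishment-limited
attainable yield (attainment drawn per field from the seasonal
percent-of-target distributions, 0.98/0.91/0.67 with their observed sd and
ranges), the second the N-supply limit. Farmer-practice N realizes a lower
AE (12) than stage-synchronized N (15), folding timing and micronutrient
disadvantages into one parameter; farmer rates are uniform around the
seasonal practice means, wide enough to generate both mining and surplus P
balances; 69% of farmer plots use a fourth top dressing and 0/15/20% apply
zinc. The generator reproduces distributions and treatment contrasts, not
real fields: passing tests demonstrate internal consistency and the
algebraic identities of the engine, not predictive skill on any actual
field.

## Numerical choices and degenerate inputs

- Rates round to 1 kg ha⁻¹; split doses to 0.5 kg with largest-remainder
  conservation; masses to 0.1 kg (0.5 kg in rendered output).
- The K rate floors at zero; the balance-equals-drawdown identity is
  asserted only when the floor is not binding.
- Ties in largest-remainder repair resolve by event order (early first).
- Interviews reject historical yields outside 3.0–8.0 Mg ha⁻¹,
  establishment before sowing, and seedling ages given for non-transplanted
  crops or ≥ the variety duration.
- Rendered recommendations contain no timestamps, so identical inputs give
  byte-identical output.

## Acceptance recomputation

`scripts/acceptance.py` reports three quantities, each computed by running
the package: the early-dose share of total N for a 135-day transplanted
variety with 25-day seedlings (PI at DAE 45, the 24/38/38 branch; a
100 kg ha⁻¹ total keeps the 0.5-kg dose grid from obscuring the
percentage); the mean P balance over 600 recommended fields (200 per
season) when each achieves its target — the population version of the
full-maintenance identity, with per-field ±0.5 kg rounding residuals
averaging out; and the labor-cost difference between four- and
three-application schedules with product costs zeroed. Problem sizes keep
the full recomputation under a minute.

## Known limitations

- Target-yield setting is a clamp rule with a single seasonal cutoff; it
  does not use sowing-date response curves, weather or crop simulation.
- K input from irrigation water is a per-season constant, not scaled by
  actual water use or measured concentration.
- The allocator handles one P source per field; mixing two P-bearing
  products in one event is out of scope, as is least-cost optimization.
- Long-term soil K trajectories under sustained negative balances are not
  modelled; the drawdown targets are short-term economic choices.
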