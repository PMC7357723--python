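# ssnmrice

Field-specific fertilizer recommendations for irrigated rice using
site-specific nutrient management (SSNM), with the economics and
nutrient-balance accounting needed to evaluate those recommendations in
on-farm trials.

Rice farmers across Asia are usually handed one blanket N–P–K dose for an
entire region, even though indigenous nutrient supply, variety, season and
residue management differ field by field. `ssnmrice` turns a short pre-season
farmer interview into a per-field plan: a target yield, elemental N/P/K
rates, a dated split-application schedule at three critical growth stages,
and the exact masses of the farmer's preferred commercial fertilizers for
the area of the field. It is written for agronomists and extension
researchers running or simulating nutrient-management trials, and is
parameterized for the three irrigated seasons of the Cauvery Delta
(kuruvai, samba, thaladi) out of the box.

## The model

For a field with reported historical yield $Y_h$ (Mg ha⁻¹) and a variety
whose locally attainable baseline window is $[B_{lo}, B_{hi}]$:

- **Target yield** — $Y_t = \mathrm{clamp}(Y_h + \Delta,\; B_{lo},\; B_{hi})$
  with season increment $\Delta$ (default 1.0 Mg ha⁻¹), reduced by a
  penalty when the crop is established after a season cutoff (15 June in
  kuruvai), and constrained to $[Y_h,\, Y_h + 2.5]$.
- **Fertilizer N** (yield-gain approach) —
  $FN = 1000\,(Y_t - Y_0)/AE$, where $Y_0$ is the yield attainable on
  indigenous N supply alone and $AE$ the agronomic efficiency of fertilizer
  N (kg grain per kg N, default 15).
- **Fertilizer P** (full maintenance) — $FP = Y_t \cdot r_P$, where $r_P$
  is the crop P removal coefficient (kg P per Mg grain, grain + exported
  straw). A field achieving its target therefore has a P balance of 0.
- **Fertilizer K** (partial maintenance) —
  $FK = \max\!\big(0,\; Y_t \cdot r_K - K_{irr} - K_{res} + K_{dd}\big)$,
  where $K_{irr}$ is seasonal K input from irrigation water (25/8/4
  kg ha⁻¹), $K_{res}$ the K returned by retained previous-crop straw, and
  $K_{dd} \le 0$ the targeted drawdown of soil K reserves (−30/−33/−4
  kg ha⁻¹ per season).
- **Scheduling** — N is split 24% / 38% / 38% over the early dose (≤ 11
  days after establishment), active tillering, and panicle initiation (PI);
  three equal doses are used instead when PI falls before day 30. All P and
  55% of K accompany the early dose; the rest of the K goes out at PI.
- **Economics** — PFP = 1000·GY/FN (kg grain per kg N); gross return above
  fertilizer cost = GY × MSP − (product cost + 9.5 US\$ ha⁻¹ per
  application); added net benefit = difference in gross return above
  fertilizer cost between two treatments on the same field, summarized by
  empirical exceedance curves and the probability of financial loss.

The fixed regional blanket recommendation (150 kg N, 22 kg P, 42 kg K
ha⁻¹ in four splits) and a farmer's-practice generator are included as
reference treatments, and a synthetic-population module reproduces the
statistical structure of a 74-field, three-season on-farm trial series so
everything is testable without any field data.

## Worked example

```
$ ssnmrice recommend examples/interview.json
FIELD-SPECIFIC FERTILIZER RECOMMENDATION
Field: CD-2014-k07    Season: kuruvai
Target yield: 5.3 Mg/ha
Fertilizer rates (elemental, kg/ha): N 120  P 14  K 28

Days after establishment  Stage              Product            kg for field
                       7  early              dap                        55.5
                       7  early              muriate_of_potash          25.0
                       7  early              urea                       48.0
                      13  active_tillering   urea                       69.5
                      20  panicle_initiation muriate_of_potash          20.0
                      20  panicle_initiation urea                       69.5
                       0  basal              zinc_sulfate               20.0

Applications: 3
Fertilizer product cost: 62.83 US$
Application labor: 28.50 US$/ha
```

The 0.8-ha field reported 4.8 Mg ha⁻¹ historically; the +1.0 increment is
clamped into the variety window and reduced by 0.5 Mg ha⁻¹ for transplanting
after 15 June, giving a 5.3 Mg ha⁻¹ target. The 120 kg N ha⁻¹ rate
(= 1000 × 1.8 / 15) is split into three equal 40-kg doses because this
short-duration crop (110 d minus 25 nursery days) reaches panicle initiation
only 20 days after transplanting. P (14 kg ha⁻¹) is covered exactly by
diammonium phosphate, whose own N counts toward the early dose before urea
tops it up; K (28 kg ha⁻¹) is split 55:45 between the early dose and PI as
muriate of potash. All masses are for the 0.8-ha field; zinc sulfate is a
fixed basal line item (25 kg ha⁻¹), not a field-specific diagnosis.

Trial-series evaluation (treatment summaries, P/K balances and
added-net-benefit exceedance curves from a trial CSV):

```
$ ssnmrice evaluate trials.csv --out results/
```

In Python, the same engine is three calls:

```python
from ssnmrice import recommend, sample_population, default_population_specs, Season

interviews, records = sample_population(default_population_specs(seed=1)[Season.SAMBA])
rec = recommend(interviews[0])
print(rec.target_yield, rec.rates)   # 6.0  n=130.0 p=16.0 k=54.0
```

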