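{
  "field_id": "CD-2014-k07",
  "field_area": 0.8,
  "season": "kuruvai",
  "irrigation_source": "tube_well",
  "variety": {
    "name": "ADT 43",
    "duration": 110,
    "baseline_yield_lo": 4.6,
    "baseline_yield_hi": 6.1
  },
  "establishment": "transplanted",
  "seedling_age": 25,
  "sowing_date": "2014-06-10",
  "establishment_date": "2014-07-05",
  "historical_yield": 4.8,
  "prev_residue": "removed",
  "prev_crop_yield": null,
  "selected_products": [
    "dap",
    "muriate_of_potash"
  ]
}
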