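# Synthetic livestock feed / crop-intensity registry (LCA-style coefficients).
#
# These are package default placeholders in the style of a life-cycle feed
# inventory: editable configuration, NOT measured data.  The scenario engine
# only requires the registry to be structurally complete and internally
# consistent; absolute feed, fertiliser-N and GHG outputs of the diet-shift
# scenarios scale directly with these numbers.
#
# feed_inventory: kg of each feed crop, kg fertiliser-N and kg CO2e emitted
#   per kg of animal product at farm gate.  GHG intensities here exclude the
#   soybean-feed share, which is accounted separately through the imported
#   soybean route (1.39 kg CO2e per kg bean).
feed_inventory:
  chicken:
    wheat: 1.70
    barley: 0.05
    maize: 0.90
    soybean: 0.60
    rapeseed: 0.08
    sunflower: 0.05
    fertiliser_n: 0.030
    ghg_co2e: 4.0
  pork:
    wheat: 1.20
    barley: 0.15
    maize: 0.60
    soybean: 0.35
    rapeseed: 0.10
    sunflower: 0.05
    fertiliser_n: 0.025
    ghg_co2e: 4.5
  milk:
    wheat: 0.10
    barley: 0.05
    maize: 0.20
    soybean: 0.04
    rapeseed: 0.03
    sunflower: 0.01
    fertiliser_n: 0.004
    ghg_co2e: 1.1

# crop_land_n_intensity: hectares and kg fertiliser-N required per tonne of
# each feed crop.  Soybean feed is excluded here (handled on the Brazilian
# import route: land via the Brazil yield, GHG via the import intensity).
crop_land_n_intensity:
  wheat:      {ha_per_t: 0.141, n_kg_per_t: 23.0}
  barley:     {ha_per_t: 0.170, n_kg_per_t: 20.0}
  maize:      {ha_per_t: 0.110, n_kg_per_t: 16.0}
  rapeseed:   {ha_per_t: 0.310, n_kg_per_t: 55.0}
  sunflower:  {ha_per_t: 0.400, n_kg_per_t: 24.0}

# protein_content: g protein per 100 g fresh product, used for the 1:1
# protein substitution of chicken and pork by soybean.
protein_content:
  soybean: 36.0
  chicken: 20.0
  pork: 16.0
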