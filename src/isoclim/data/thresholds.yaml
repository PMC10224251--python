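# Rivas-Martinez 2011 worldwide bioclimatic classification: threshold tables.
# Intervals are lower-closed, upper-open. Each class splits into two horizons
# at its midpoint; `high_value_horizon` names the horizon occupying the upper
# half of the value range. For thermotypes the "upper" horizon is the colder
# (lower-index) half, matching field usage (upper belts sit higher upslope).
version: 1
itc_validity_floor: 120.0
submediterranean_ios3_max: 2.0
axes:
  ombrotype:
    variable: io
    horizon_labels: [lower, upper]
    high_value_horizon: upper
    classes:
      - {name: ultrahyperarid, lo: 0.0, hi: 0.2}
      - {name: hyperarid, lo: 0.2, hi: 0.4}
      - {name: arid, lo: 0.4, hi: 1.0}
      - {name: semiarid, lo: 1.0, hi: 2.0}
      - {name: dry, lo: 2.0, hi: 3.6}
      - {name: subhumid, lo: 3.6, hi: 6.0}
      - {name: humid, lo: 6.0, hi: 12.0}
      - {name: hyperhumid, lo: 12.0, hi: 24.0}
      - {name: ultrahyperhumid, lo: 24.0, hi: 1000.0}
  continentality:
    variable: ic
    horizon_labels: [weak, strong]
    high_value_horizon: strong
    classes:
      - {name: ultrahyperoceanic, lo: 0.0, hi: 4.0}
      - {name: euhyperoceanic, lo: 4.0, hi: 8.0}
      - {name: subhyperoceanic, lo: 8.0, hi: 11.0}
      - {name: semihyperoceanic, lo: 11.0, hi: 14.0}
      - {name: euoceanic, lo: 14.0, hi: 17.0}
      - {name: semicontinental, lo: 17.0, hi: 21.0}
      - {name: subcontinental, lo: 21.0, hi: 28.0}
      - {name: eucontinental, lo: 28.0, hi: 46.0}
      - {name: hypercontinental, lo: 46.0, hi: 66.0}
  thermotype_mediterranean:
    variable: itc
    horizon_labels: [lower, upper]
    high_value_horizon: lower
    classes:
      - {name: supramediterranean, lo: 120.0, hi: 220.0}
      - {name: mesomediterranean, lo: 220.0, hi: 350.0}
      - {name: thermomediterranean, lo: 350.0, hi: 450.0}
      - {name: inframediterranean, lo: 450.0, hi: 580.0}
    # Used when Itc falls below the validity floor (cold belts).
    tp_classes:
      - {name: cryoromediterranean, lo: 1.0, hi: 450.0}
      - {name: oromediterranean, lo: 450.0, hi: 900.0}
      - {name: supramediterranean, lo: 900.0, hi: 1500.0}
      - {name: mesomediterranean, lo: 1500.0, hi: 2150.0}
  thermotype_temperate:
    variable: itc
    horizon_labels: [lower, upper]
    high_value_horizon: lower
    classes:
      - {name: supratemperate, lo: 120.0, hi: 190.0}
      - {name: mesotemperate, lo: 190.0, hi: 300.0}
      - {name: thermotemperate, lo: 300.0, hi: 410.0}
      - {name: infratemperate, lo: 410.0, hi: 580.0}
    tp_classes:
      - {name: cryorotemperate, lo: 1.0, hi: 380.0}
      - {name: orotemperate, lo: 380.0, hi: 800.0}
      - {name: supratemperate, lo: 800.0, hi: 1200.0}
      - {name: mesotemperate, lo: 1200.0, hi: 1700.0}
bioclimate:
  mediterranean:
    # ombrothermic regime from Io, oceanicity from Ic (< split -> oceanic)
    regimes:
      - {name: hyperdesertic, lo: 0.0, hi: 0.2}
      - {name: desertic, lo: 0.2, hi: 1.0}
      - {name: xeric, lo: 1.0, hi: 2.0}
      - {name: pluviseasonal, lo: 2.0, hi: 1000.0}
    oceanic_ic_max: 21.0
  temperate:
    classes:
      - {name: hyperoceanic, lo: 0.0, hi: 11.0}
      - {name: oceanic, lo: 11.0, hi: 21.0}
      - {name: continental, lo: 21.0, hi: 66.0}
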