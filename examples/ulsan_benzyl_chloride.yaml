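# Packaged example: 40 t of benzyl chloride released over one hour at
# midnight on 1 January 2017 from the centre of a 16 km x 12 km
# industrial-complex domain (100 m cells, 10 m surface layer), with a
# synthetic north-westerly prevailing wind so the plume trends
# south-east.  Re-volatilization is enabled so deposited soil mass
# sustains a slowly decaying air signal, giving a multi-week extinction
# endpoint.
scenario:
  chemical:
    name: benzyl chloride
    molecular_weight: 126.58
    csf_oral: 0.17
    background_air_ppb: 0.01
    air_decay_rate: 0.0144        # 1/h, ~2-day half-life
    soil_decay_rate: 0.015        # 1/day; scenario calibration, see docs/methods.md
    deposition_velocity: 0.005    # m/s
  release_mass_kg: 40000
  release_duration_h: 1
  start_time: 2017-01-01T00:00:00
  horizon_days: 100
  grid:
    nx: 160
    ny: 120
    dx: 100
    dy: 100
    mixing_height: 10
    origin: [0, 0]
    source_cell: [80, 60]
meteo:
  source: synthetic
  seed: 2017
  prevailing_from_direction: 315   # from NW; plume travels SE
  direction_spread: 35
  speed_mean: 2.5
  speed_sd: 1.2
  stability_weights: [0.05, 0.10, 0.15, 0.40, 0.15, 0.15]
fate:
  n_substeps: 6
  soil:
    bulk_density: 1300
    mixing_depth: 0.01
  revolatilization_rate: 2.5e-05   # 1/day; scenario calibration, see docs/methods.md
  export_buffer_m: 5000
endpoint:
  background_ppb: 0.01
  molar_volume_l: 24.45
risk:
  csf: 0.17
  thresholds:
    red: 1.0e-06
    orange: 1.0e-07
out_dir: chemrisk_out/ulsan
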