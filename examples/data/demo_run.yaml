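# Demonstration run: simulate a small two-region founder scenario (one pulse
# at 40 ka, star-like growth on both sides, infinite-sites HVS-I mutation
# model so the median network is reticulation-free) and push it through the
# full pipeline: network -> dating -> founder scan -> diversity.
seed: 7
scenario:
  source: {n_samples: 10, trajectory: star}
  sink: {n_samples: 10, trajectory: star}
  founder_events:
    - {time_years: 40000, n_founders: 1}
  clock: hvs1
  site_model: {n_sites: 1500, infinite_sites: true}
  seed: 7
network:
  r: 2.0
  max_nodes: 20000
founder:
  criterion: f1
  clock: hvs1
  grid_step: 200
  t_max: 120000
  sink_filter: "region == 'southern'"
  tree: network
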