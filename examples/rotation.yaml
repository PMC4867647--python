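# Two-year maize / winter-wheat rotation on the bundled sandy profile.
# Generate the weather first:
#   whcns make-weather --seed 1 --years 3 --out examples/weather.csv
simulation:
  start_date: 2000-01-01
  end_date: 2002-01-01
  profile_depth: 150.0
  node_spacing: 5.0
weather: weather.csv
events: events_rotation.csv
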