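# Example run configuration for the `dissonet` command line.
#
#   dissonet descriptives -c config_example.yaml
#   dissonet fit          -c config_example.yaml
#   dissonet gof          -c config_example.yaml
#   dissonet logodds      -c config_example.yaml --attribute pwb --low 20 --high 79
#
# Input files use the roster CSV dialects:
#   edge lists:  header `sender,receiver`, one nomination per row
#   attributes:  header `id,gender,pwb,smf,ses`, complete cases only

friendship: data/friendship.csv   # friendship nominations
dislike: data/dislike.csv         # dislike nominations (or item 2a)
# dislike_b: data/dislike_b.csv   # optional second dislike item, merged either/or

attributes: data/attributes.csv

# gender groups analysed separately; omit to use every label found
groups: [boy, girl]

output_dir: results_run1
seed: 1                           # every stochastic step derives from this

# model: either the built-in full cohort specification ...
model: cohort
# ... or an explicit ordered effect list:
# model:
#   - {kind: arc, layer: F}
#   - {kind: arc, layer: D}
#   - {kind: reciprocity, layer: F}
#   - {kind: exchange, layer: cross}
#   - {kind: mutual_sum_exchange, layer: cross, attribute: pwb}

# estimation settings (all optional; defaults sized for n ~ 60)
estimation:
  phase1_samples: 100
  subphase_iterations: [100, 200, 400, 800]
  initial_gain: 0.1
  phase3_samples: 1000
  max_retries: 3
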