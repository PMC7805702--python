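# Full-scale protocol: N=40, G=3000, T=200 s episodes at S=0.02.
# Sweep B/W/P on the command line:
#   nichesim sweep --config configs/full_scale.yaml \
#       --b 10 --b 20 --b 30 --b 40 --w 1.0 --p False --trials 10 --out full.csv
world:
  field_width: 1000.0
  field_height: 400.0
  tile_side: 20.0
  agent_radius: 20.0
  box_side: 18.0
  timestep: 0.02
  prey_start: [400.0, 50.0]
  predator_start: [900.0, 50.0]
prey:
  f_prey: 500.0
  l_prey: 250.0
  budget: 40
  hidden_size: 10
predator:
  f_predator: 1000.0
ga:
  n: 40
  generations: 3000
  pc: 0.7
  pm: 0.001
  r: 0.003
eval:
  t_limit: 200.0
  timestep: 0.02
inherit:
  w: 1.0
  p: false
n_trials: 10
master_seed: 0
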