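# Reintroduction demography of the Alpine ibex, full parametrization.
#
# One deme (gp, Gran Paradiso) represents the species through a 3000-
# generation burn-in at K = 1000, deliberately too short for mutation-
# drift-selection equilibrium so deleterious variants still segregate.
# The species bottleneck reduces K to 500 for five generations, then to 80
# for two; recovery to 1000 at generation 3007; reintroduction starts three
# generations later with the founding of two zoo populations, followed by
# wild populations in simplified phases.
#
# Patch codes: gp Gran Paradiso, ih Zoo Interlaken Harder, pp Wildpark
# Peter and Paul, al Albris, br Brienzer Rothorn, pl Pleureur, am Alpi
# Marittime, bo Bire Oeschinen, ob Oberbauenstock, rh Rheinwald,
# wh Weisshorn, pi Pilatus.
#
# Carrying capacities are harmonic means of the census record from founding
# to 2007.  Zoo capacities (historical harmonic means ih = 16, pp = 20) are
# adjusted upwards to keep the zoos viable.  Founder counts and wild-patch
# capacities marked "estimated" are transcribed estimates, not published
# point values; edit them here rather than in code.
patches:
  - {name: gp, k: 1000}
  - {name: ih, k: 0}
  - {name: pp, k: 0}
  - {name: al, k: 0}
  - {name: br, k: 0}
  - {name: pl, k: 0}
  - {name: am, k: 0}
  - {name: bo, k: 0}
  - {name: ob, k: 0}
  - {name: rh, k: 0}
  - {name: wh, k: 0}
  - {name: pi, k: 0}
burn_in: {patch: gp, generations: 3000}
events:
  # species bottleneck and recovery
  - {type: set_k, generation: 3000, patch: gp, k: 500}
  - {type: set_k, generation: 3005, patch: gp, k: 80}
  - {type: set_k, generation: 3007, patch: gp, k: 1000}
  # phase 1: zoo foundings (k upwards adjusted from harmonic means 16 / 20)
  - {type: found, generation: 3010, patch: ih, sources: {gp: 10}, k: 25}  # estimated founders
  - {type: found, generation: 3010, patch: pp, sources: {gp: 12}, k: 30}  # estimated founders
  # phase 2: first wild populations; am translocated directly from gp (25 released)
  - {type: found, generation: 3013, patch: al, sources: {ih: 6, pp: 6}, k: 500}   # estimated
  - {type: found, generation: 3013, patch: br, sources: {ih: 10}, k: 400}         # estimated
  - {type: found, generation: 3013, patch: pl, sources: {pp: 14}, k: 250}         # estimated
  - {type: found, generation: 3013, patch: am, sources: {gp: 25}, k: 50}          # k estimated
  # phase 3: secondary foundings
  - {type: found, generation: 3016, patch: bo, sources: {al: 12}, k: 100}  # estimated
  - {type: found, generation: 3016, patch: ob, sources: {al: 8}, k: 80}    # estimated
  - {type: found, generation: 3016, patch: rh, sources: {pl: 18}, k: 300}  # estimated
  - {type: found, generation: 3016, patch: wh, sources: {pl: 10}, k: 150}  # estimated
  - {type: found, generation: 3016, patch: pi, sources: {br: 6}, k: 100}   # estimated
end_generation: 3022
snapshots: [2999, 3009, 3022]
report_every: 0
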