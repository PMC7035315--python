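# Desk-scale counterpart of ibex_reintroduction.yaml: carrying capacities
# divided by ten (floored at viability), burn-in shortened to 300
# generations, founder counts reduced to stay drawable from the smaller
# sources.  Intended for tests and quick exploration with
# SelectionParams(n_deleterious_loci=500, n_neutral_loci=100).
patches:
  - {name: gp, k: 100}
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
burn_in: {patch: gp, generations: 300}
events:
  - {type: set_k, generation: 300, patch: gp, k: 50}
  - {type: set_k, generation: 305, patch: gp, k: 8}
  - {type: set_k, generation: 307, patch: gp, k: 100}
  - {type: found, generation: 310, patch: ih, sources: {gp: 6}, k: 12}
  - {type: found, generation: 310, patch: pp, sources: {gp: 6}, k: 12}
  - {type: found, generation: 313, patch: al, sources: {ih: 3, pp: 3}, k: 50}
  - {type: found, generation: 313, patch: br, sources: {ih: 4}, k: 40}
  - {type: found, generation: 313, patch: pl, sources: {pp: 4}, k: 25}
  - {type: found, generation: 313, patch: am, sources: {gp: 12}, k: 10}
  - {type: found, generation: 316, patch: bo, sources: {al: 6}, k: 10}
  - {type: found, generation: 316, patch: ob, sources: {al: 4}, k: 8}
  - {type: found, generation: 316, patch: rh, sources: {pl: 6}, k: 30}
  - {type: found, generation: 316, patch: wh, sources: {pl: 5}, k: 15}
  - {type: found, generation: 316, patch: pi, sources: {br: 4}, k: 10}
end_generation: 322
snapshots: [299, 309, 322]
report_every: 0
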