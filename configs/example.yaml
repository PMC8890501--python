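# Full-scale run emulating the study design: 4^7 library, 8-point magnesium
# titration in triplicate, Wright-Fisher simulations on every landscape.
# Override the seed with `ribolandscape all --seed N --out DIR`.
seed: 1
library:
  mg_levels: [1, 2, 3, 4, 6, 8, 16, 48]
  replicates: 3
generator:
  read_depth: 1000000
simulation:
  population_size: 1000
  mutation_rate: 0.01
  generations: 2000
  replicates: 100
stages: [simulate, count, fitness, topography, doseresponse, evolve]
emit_fastq: false  # write count tables directly; set true to exercise FASTQ I/O
contaminant_fraction: 0.0
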