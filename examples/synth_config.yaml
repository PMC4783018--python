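# Shipped synthetic study: two contrasting areas on a 48x48, 30 m grid.
# Genetic distances are generated from a known "true" resistance surface
# (forest 100, development 250, roads 250 as barriers; scrub-shrub,
# powerline and railroad as facilitators), so the pipeline's output tables
# can be read against a known answer.
outdir: scratch/synth_run
seed: 42
shape: [48, 48]
cell_size: 30.0
areas:
  - name: kittery_like
    n_individuals: 18
  - name: cape_like
    n_individuals: 18
n_perm: 99
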