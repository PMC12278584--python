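# Desk-scale pipeline configuration: 8 taxa, 20 loci, short codon
# alignments, moderate incomplete lineage sorting.  Study-scale values
# (56 taxa, 100 loci, 100-1600 codons, occupancy 34-50) are the SimConfig
# defaults; this file overrides them for a quick run.
sim:
  n_taxa: 8
  n_loci: 20
  n_codons_range: [50, 70]
  coal_scale: 0.7
  short_branch_fraction: 0.3
  subst_scale: 0.08
  occupancy_range: [6, 8]
n_target: 4        # retained loci, balanced between the two model families
alpha: 0.05
seed: 1
n_starts: 2        # optimization starts per refit
n_cat: 1           # gamma rate categories for the desk-scale run
coarse_refits: true
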