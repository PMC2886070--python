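# Full emulated study design: 3 species, 9404-gene transcript universe,
# 1489 proteins with 1074 loci shared, triplicate proteomics, 12
# metabolite replicates per species, 10% of shared loci regulated.
simulate:
  frac_de: 0.1
  de_log2fc: 2.0
  coupling_rho: 0.5
alpha: 0.05
spectral_fraction: 0.5
n_perm: 10000
seed: 42
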