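# Cyanobacteria chemostat series subsampled to 454 points: half-length mu
# scale, full-length phi scale (index units).
rho_mu: 227
rho_phi: 454
chains: 4
warmup: 1000
draws: 1000
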