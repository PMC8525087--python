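# Ocean-sediment CaCO3 proxy series (428 points): short mean length scale,
# long phi length scale (index units).
rho_mu: 15
rho_phi: 100
chains: 4
warmup: 1000
draws: 1000
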