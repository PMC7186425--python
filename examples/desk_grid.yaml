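# Desk-scale factorial: cooperative vs independent genomic programs over rg
scenarios: [AG-AS, WG-WS]
h2_levels: [0.3]
rg_levels: [0.8, 0.85, 0.9]
pop_mode: equal
scale: desk
n_replicates: 10
seed: 1
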