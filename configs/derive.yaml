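# Derivation settings for the demonstration chain: 20 PCs, all four
# percentile schemes compared by entropy at K=3, class count chosen by BIC
# followed by the bootstrap likelihood-ratio test (99 replicates here; the
# library default is 999).
n_components: 20
scheme_k: 3
k_max: 4
n_bootstrap: 99
n_starts: 10
random_state: 20
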