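{
 "diversity_summary.tsv": "33d5eb8f7335c75c0c788b12e84666eb1cccd0e305eeaecaaa8b72ca1b4ab368",
 "fst_mutation_patterns.tsv": "3bf0fe12316bba656d1cba0d3051f1459c70197293e8b5f732519bdc17d9cfe4",
 "loss_of_diversity.tsv": "9adf167ce7ed9741a9f06fb19a9c645cd6a128665350a89c7bc34f4ef3af9749",
 "mutation_effect_counts.tsv": "317adc2c0de22533b10505f60741dca21567d15534e1ffd733012a808bb9ae62"
}
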