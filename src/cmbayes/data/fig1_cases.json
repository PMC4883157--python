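[
  {"name": "always_dominant", "matrix": [[90, 0], [10, 0]], "n_reps": 1},
  {"name": "errors_in_dominant", "matrix": [[80, 10], [0, 10]], "n_reps": 1},
  {"name": "perfect", "matrix": [[90, 0], [0, 10]], "n_reps": 1},
  {"name": "random_uniform", "matrix": [[45, 45], [5, 5]], "n_reps": 1}
]
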