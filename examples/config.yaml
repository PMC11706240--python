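# Example run configuration for `satbench simulate` / `satbench benchmark`.
# CLI flags override these values.
seed: 123
design: {}            # ExperimentDesign field overrides, e.g. trials_per_block: 210
humans:
  synthetic:
    n_observers: 5
    experiment: gray_noise
    # base psychometric parameters (population jitter is applied on top)
    # gamma: 0.0625
    # lam: 0.22
    # tau: 1150.0
    # beta: 3.5
models:
  synthetic:
    gradual_wide: {n_images: 150}
    steep_saturating: {n_images: 150}
    shallow_low_range: {n_images: 150}
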