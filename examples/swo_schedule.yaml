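# Slow-wave schedule for `thalamica swo`: low-dose trough-max half, then a
# high-dose, hyperpolarized peak-max half. Durations in ms; background
# excitation in uA/cm^2 adds to the config baseline.
- {state: DOWN, duration: 650.0, dose_multiplier: 2.0, background_excitation: 0.2}
- {state: UP, duration: 350.0, dose_multiplier: 2.0, background_excitation: 0.4}
- {state: DOWN, duration: 650.0, dose_multiplier: 2.0, background_excitation: 0.2}
- {state: UP, duration: 350.0, dose_multiplier: 2.0, background_excitation: 0.4}
- {state: DOWN, duration: 650.0, dose_multiplier: 2.0, background_excitation: 0.2}
- {state: UP, duration: 350.0, dose_multiplier: 2.0, background_excitation: 0.4}
- {state: DOWN, duration: 500.0, dose_multiplier: 3.0, background_excitation: -0.6}
- {state: UP, duration: 500.0, dose_multiplier: 3.0, background_excitation: -0.5}
- {state: DOWN, duration: 500.0, dose_multiplier: 3.0, background_excitation: -0.6}
- {state: UP, duration: 500.0, dose_multiplier: 3.0, background_excitation: -0.5}
- {state: DOWN, duration: 500.0, dose_multiplier: 3.0, background_excitation: -0.6}
- {state: UP, duration: 500.0, dose_multiplier: 3.0, background_excitation: -0.5}
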