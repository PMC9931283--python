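import numpy as np


def make_random_epochs(rng: np.random.Generator, n_epochs: int, spe: int = 3000):
    """Random but physically plausible epochs: unit-gravity direction plus a
    quasi-periodic component and noise, mixed with plain-noise epochs."""
    epochs = []
    t = np.arange(spe) / 100.0
    for k in range(n_epochs):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        drift = d + np.cumsum(rng.normal(0, 0.002, size=(spe, 3)), axis=0)
        drift /= np.linalg.norm(drift, axis=1, keepdims=True)
        if k % 3 == 0:
            mag = 1.0 + rng.normal(0, 0.02, size=spe)
        else:
            amp = rng.uniform(0.05, 0.3)
            freq = rng.uniform(1.5, 2.2)
            mag = 1.0 + amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
            mag += rng.normal(0, 0.03, size=spe)
        epochs.append(mag[:, None] * drift)
    return epochs
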