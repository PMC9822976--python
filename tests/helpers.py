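"""Shared test utilities (imported by test modules, not a test file)."""

import numpy as np

from acertail import MergedVector


def random_merged(rng, n, n_components=3):
    """Random merged vector with unit limits and sorted integer times."""
    values = rng.uniform(0.0, 1.0, n)
    times = np.sort(rng.integers(0, n, n)).astype(float)
    source = rng.choice([f"C{i}" for i in range(n_components)], n).astype(object)
    return MergedVector(
        values=values,
        times=times,
        source=source,
        limits=np.ones(n),
        span_t=float(max(times.max() - times.min() + 1, 1)),
        n_components=n_components,
    )
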