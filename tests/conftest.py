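import numpy as np
import pandas as pd
import pytest

import puppygrowth as pg


def make_records(p0_by_puppy, days=None, coeffs=None, noise_sd=0.0, seed=0,
                 sex=None, breed="X", litter="L"):
    """Long-format weight records generated exactly from the growth law.

    ``p0_by_puppy`` maps puppy_id -> P0 in grams; optional multiplicative
    log-normal noise with a fixed seed.
    """
    coeffs = coeffs or pg.PUBLISHED_COEFFS
    days = np.arange(22) if days is None else np.asarray(days)
    rng = np.random.default_rng(seed)
    rows = []
    for i, (pid, p0) in enumerate(p0_by_puppy.items()):
        s = sex[pid] if sex else ("male" if i % 2 else "female")
        w = p0 * coeffs.growth_factor(days.astype(float))
        if noise_sd > 0:
            w = w * np.exp(rng.normal(0.0, noise_sd, len(days)))
        for d, wd in zip(days, w):
            rows.append(
                dict(puppy_id=pid, litter_id=litter, breed=breed, sex=s,
                     day=int(d), weight_g=float(wd))
            )
    return pd.DataFrame(rows)


@pytest.fixture
def five_puppies_exact():
    """Noise-free series for five puppies spanning the birth-weight range."""
    return make_records({f"P{i}": p0 for i, p0 in
                         enumerate([150.0, 250.0, 350.0, 450.0, 600.0])})
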