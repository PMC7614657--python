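"""Single-cell dose-response table generator.

Draws per-cell ND-CDT1 expression log-uniformly over a configured range
and computes EdU incorporation from the Hill model with multiplicative
lognormal noise (mean 1, configurable coefficient of variation), floored
at zero. The instantaneous Hill value stands in for the short-pulse
average incorporation rate; pulse kinetics are absorbed into the noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..stats import DoseResponseFit

__all__ = ["sample_dose_response"]


def sample_dose_response(
    fit: DoseResponseFit,
    n: int,
    noise_cv: float,
    expression_range: tuple[float, float] = (0.5, 40.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate ``n`` cells of (ndcdt1, edu) from a Hill dose-response.

    ND-CDT1 is log-uniform over ``expression_range``; EdU is the Hill
    prediction times lognormal noise with mean 1 and CV ``noise_cv``,
    floored at 0. Deterministic given ``seed``.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    lo, hi = expression_range
    if lo <= 0 or hi <= lo:
        raise ValueError("expression_range must be positive and increasing")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    ndcdt1 = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    edu = fit.predict(ndcdt1)
    if noise_cv > 0:
        sigma2 = np.log1p(noise_cv**2)
        noise = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)
        edu = edu * noise
    edu = np.maximum(edu, 0.0)
    return pd.DataFrame({"ndcdt1": ndcdt1, "edu": edu})
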