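"""Independent estimators used to cross-check the package implementations.

These deliberately avoid the code paths they validate: variance
components come from the one-way ANOVA method-of-moments identities, not
from a mixed-model fit.
"""

import numpy as np
import pandas as pd


def anova_variance_components(values, groups):
    """Method-of-moments one-way variance components (unbalanced-safe).

    MSW = SSW / (N - k); MSB = SSB / (k - 1);
    s2_w = MSW; s2_b = (MSB - MSW) / n0 with
    n0 = (N - sum n_i^2 / N) / (k - 1)  (equals the common group size
    when the design is balanced).
    """
    df = pd.DataFrame({"y": np.asarray(values, float), "g": np.asarray(groups)})
    grand = df["y"].mean()
    stats = df.groupby("g")["y"].agg(["count", "mean"])
    n_i = stats["count"].to_numpy(float)
    means = stats["mean"].to_numpy()
    N, k = len(df), len(stats)
    ssw = ((df["y"] - df.groupby("g")["y"].transform("mean")) ** 2).sum()
    ssb = (n_i * (means - grand) ** 2).sum()
    msw = ssw / (N - k)
    msb = ssb / (k - 1)
    n0 = (N - (n_i**2).sum() / N) / (k - 1)
    s2b = max((msb - msw) / n0, 0.0)
    return s2b, msw
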