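"""Independent closed-form oracles used across the test suite.

These deliberately avoid the package's own code paths: least squares
by explicit normal equations, ANOVA left to scipy.stats.f_oneway on
raw data where used.
"""

import numpy as np


def ols_oracle(x, y):
    """Normal-equations least squares: slope, intercept, residual sd
    (n-2 dof), slope sd, intercept sd."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - (slope * x + intercept)
    syx = np.sqrt(resid @ resid / (n - 2))
    centred_sxx = sxx - sx * sx / n
    slope_sd = syx / np.sqrt(centred_sxx)
    intercept_sd = syx * np.sqrt(sxx / (n * centred_sxx))
    return slope, intercept, syx, slope_sd, intercept_sd
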