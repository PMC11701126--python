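"""Linear DNA-methylation age prediction with a minimum-coverage rule.

Per-CpG methylation fractions are trusted only at >= 3x read coverage
(coverage exactly 3 is kept); filtered entries become missing. Predicted
age is the clock's linear combination ``intercept + sum_i w_i * beta_i``
over its sites, imputing a missing site with the clock's training-mean
beta. Samples with less than ``min_site_fraction`` of clock sites observed
are flagged but still reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ClockModel, MethylationMatrix, ValidationError


def coverage_filter(meth: MethylationMatrix, min_cov: int = 3) -> MethylationMatrix:
    """Mask beta wherever coverage < ``min_cov`` (boundary kept)."""
    low = meth.coverage.to_numpy() < min_cov
    beta = meth.beta.to_numpy(dtype=float).copy()
    beta[low] = np.nan
    cov = meth.coverage.to_numpy().copy()
    cov[low] = 0
    return MethylationMatrix(
        beta=pd.DataFrame(beta, index=meth.beta.index, columns=meth.beta.columns),
        coverage=pd.DataFrame(cov, index=meth.coverage.index, columns=meth.coverage.columns),
    )


def predict_age(
    meth: MethylationMatrix,
    clock: ClockModel,
    min_site_fraction: float = 0.8,
) -> pd.DataFrame:
    """Predicted age per sample: (sample, age, n_sites_used, flagged).

    Clock sites absent from the matrix — or masked by the coverage filter —
    are imputed with the clock's training-mean beta; ``flagged`` marks
    samples with fewer than ``min_site_fraction`` of clock sites observed.
    """
    sites = pd.Index(clock.sites)
    present_sites = sites.intersection(meth.beta.index)
    if len(present_sites) == 0:
        raise ValidationError("no clock site present in the methylation matrix")
    beta = meth.beta.reindex(sites)  # missing sites become all-NaN rows
    w = clock.weights.to_numpy(dtype=float)
    tm = clock.training_mean.to_numpy(dtype=float)
    b = beta.to_numpy(dtype=float)
    observed = ~np.isnan(b)
    filled = np.where(observed, b, tm[:, None])
    ages = clock.intercept + filled.T @ w
    n_used = observed.sum(axis=0)
    frac = n_used / len(sites)
    return pd.DataFrame(
        {
            "sample": meth.samples,
            "age": ages,
            "n_sites_used": n_used,
            "site_fraction": frac,
            "flagged": frac < min_site_fraction,
        }
    ).set_index("sample")
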