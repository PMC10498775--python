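"""Parameter-recovery accuracy criteria across replications.

For a scalar truth with point estimates across R replications:

  bias = mean(est - truth)
  mse  = mean((est - truth)^2)          (squared-error convention; the
                                         root is exposed separately as rmse)
  se   = sqrt(mean((est - mean(est))^2))  (replication scatter)
  sd   = mean of the per-replication posterior SDs

These satisfy the exact variance decomposition mse = se^2 + bias^2, which
is asserted on every run.  Block averages are arithmetic means of each
criterion across the J items (or N persons for the abilities).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np
import pandas as pd

__all__ = [
    "RecoveryReport",
    "recovery_for_parameter",
    "average_recovery",
    "recovery_table",
    "rmse",
]


@dataclass(frozen=True)
class RecoveryReport:
    """Average Bias / MSE / SE / SD for one parameter block."""

    bias: float
    mse: float
    se: float
    sd: float

    @property
    def rmse(self) -> float:
        return float(np.sqrt(self.mse))


def recovery_for_parameter(estimates, truth, posterior_sds):
    """(bias, mse, se, sd) for one scalar parameter over R replications."""
    est = np.asarray(estimates, dtype=float)
    sds = np.asarray(posterior_sds, dtype=float)
    if est.size == 0:
        raise ValueError("need at least one replication")
    if est.shape != sds.shape:
        raise ValueError("estimates and posterior_sds must have equal length")
    err = est - float(truth)
    bias = float(err.mean())
    mse = float((err ** 2).mean())
    se = float(np.sqrt(((est - est.mean()) ** 2).mean()))
    sd = float(sds.mean())
    # exact identity, up to float rounding
    assert abs(mse - (se ** 2 + bias ** 2)) <= 1e-9 * max(1.0, mse)
    return bias, mse, se, sd


def rmse(estimates, truth) -> float:
    est = np.asarray(estimates, dtype=float)
    return float(np.sqrt(((est - float(truth)) ** 2).mean()))


def average_recovery(estimates, truths, posterior_sds) -> RecoveryReport:
    """Average the four criteria over the parameters of one block.

    ``estimates`` and ``posterior_sds`` are (R, K) arrays (replications x
    parameters), ``truths`` a length-K vector.
    """
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    sds = np.atleast_2d(np.asarray(posterior_sds, dtype=float))
    truths = np.atleast_1d(np.asarray(truths, dtype=float))
    if est.shape != sds.shape or est.shape[1] != truths.size:
        raise ValueError("shape mismatch between estimates, sds, truths")
    rows = [recovery_for_parameter(est[:, k], truths[k], sds[:, k])
            for k in range(truths.size)]
    arr = np.asarray(rows)
    return RecoveryReport(*(float(v) for v in arr.mean(axis=0)))


def recovery_table(reports: Dict[str, RecoveryReport]) -> pd.DataFrame:
    """Parameter-block rows x Bias/MSE/SE/SD columns."""
    return pd.DataFrame(
        {name: {"Bias": r.bias, "MSE": r.mse, "SE": r.se, "SD": r.sd}
         for name, r in reports.items()}
    ).T[["Bias", "MSE", "SE", "SD"]]
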