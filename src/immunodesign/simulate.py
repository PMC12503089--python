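"""Synthetic antibody measurements under the assumed data-generating process.

Subjects measured on a shared schedule are drawn i.i.d. from a multivariate
normal with the kinetics mean at each sampling time and the index-based
AR(1) covariance.  Negative concentrations are allowed - the normal model
permits them and no truncation is applied, keeping the generator faithful
to the model the Fisher information is derived from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fim import ar1_covariance
from .kinetics import mean_concentration
from .types import CurveParameters, Design, ErrorModel, InitialInformation

__all__ = ["SimulatedPanel", "simulate_measurements"]


@dataclass(frozen=True)
class SimulatedPanel:
    """Measurements of ``n_subjects`` subjects on one shared schedule.

    ``observations[i, j]`` is subject i's concentration at ``times[j]``.
    Reproducible from ``seed`` (NumPy PCG64 generator).
    """

    times: np.ndarray
    observations: np.ndarray
    seed: int

    @property
    def n_subjects(self) -> int:
        return self.observations.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (subject, time, value)."""
        n, m = self.observations.shape
        return pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), m),
                "time": np.tile(self.times, n),
                "value": self.observations.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate_measurements(
    design: Design,
    params: CurveParameters,
    info: InitialInformation,
    error: ErrorModel,
    n_subjects: int,
    seed: int,
) -> SimulatedPanel:
    """Draw a panel of synthetic measurements at the design's times."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    times = design.times_array
    mean = np.atleast_1d(mean_concentration(times, params, info))
    cov = ar1_covariance(len(times), error)
    rng = np.random.default_rng(seed)
    obs = rng.multivariate_normal(mean, cov, size=n_subjects, method="cholesky")
    return SimulatedPanel(times=times, observations=obs, seed=seed)
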