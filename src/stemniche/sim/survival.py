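"""Survival-table generator with a biomarker-dependent exponential hazard."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import InvalidConfigError


def simulate_survival(
    n: int,
    log_hr: float,
    censor_rate: float,
    seed: int,
    baseline_hazard: float = 0.05,
) -> pd.DataFrame:
    """Biomarker ~ Normal(0,1); event time exponential with hazard
    ``baseline_hazard * exp(log_hr * biomarker)``; independent exponential
    censoring calibrated so roughly ``censor_rate`` of subjects are censored.

    Returns columns: subject_id, time, event, biomarker.
    """
    if n < 10:
        raise InvalidConfigError("n must be >= 10")
    if not 0.0 <= censor_rate < 1.0:
        raise InvalidConfigError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    biomarker = rng.normal(0.0, 1.0, size=n)
    hazard = baseline_hazard * np.exp(log_hr * biomarker)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0.0:
        # censoring hazard c solves c/(c+h) = censor_rate for typical h
        c = baseline_hazard * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / c, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:05d}" for i in range(n)],
            "time": time,
            "event": event,
            "biomarker": biomarker,
        }
    )
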