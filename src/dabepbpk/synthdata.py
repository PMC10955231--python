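"""Synthetic in vitro and clinical-like datasets from known ground truth.

No clinical profiles are redistributable, so every estimation pathway in
the package is exercised against data generated here: first-order plasma
decay incubations, Michaelis-Menten rate-vs-concentration designs, and
sparse plasma concentration-time observations with multiplicative
log-normal assay error and lower-limit-of-quantification censoring.  All
generators are bit-reproducible by seed, and at zero noise each generator
composed with its fitter is the identity — the module's core guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidDataError, InvalidParameterError
from .ivive import InVitroDecayDataset, MMKineticsDataset

__all__ = ["NoiseModel", "gen_invitro_decay", "gen_mm_rates",
           "gen_pk_observations"]


@dataclass
class NoiseModel:
    """Multiplicative log-normal assay error with optional LLOQ censoring."""

    cv_percent: float
    seed: int
    lloq: float = 0.0

    def __post_init__(self):
        if self.cv_percent < 0:
            raise InvalidParameterError("cv_percent must be >= 0")
        if self.seed is None:
            raise InvalidParameterError("seed is mandatory")

    def sigma(self) -> float:
        return float(np.sqrt(np.log(1.0 + (self.cv_percent / 100.0) ** 2)))

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.cv_percent == 0:
            return np.asarray(values, dtype=float).copy()
        factors = np.exp(self.sigma() * rng.standard_normal(np.shape(values)))
        return np.asarray(values, dtype=float) * factors


def gen_invitro_decay(rate_h, times_min, n_replicates: int,
                      noise: NoiseModel, c0: float = 1.0) -> InVitroDecayDataset:
    """Plasma-stability incubation: C(t) = C0*exp(-k*t), or a constant
    series for a stable compound (``rate_h='stable'``).

    Replicate noise streams derive deterministically from the master seed.
    """
    times = np.asarray(times_min, dtype=float)
    if isinstance(rate_h, str):
        if rate_h != "stable":
            raise InvalidParameterError(f"unknown rate spec {rate_h!r}")
        truth = np.full(times.shape, c0)
    else:
        if rate_h < 0:
            raise InvalidParameterError("decay rate must be >= 0")
        truth = c0 * np.exp(-rate_h / 60.0 * times)  # rate 1/h, times min
    rng = np.random.default_rng(noise.seed)
    reps = np.vstack([noise.apply(truth, rng) for _ in range(n_replicates)])
    return InVitroDecayDataset(times=times, concentrations=reps,
                               initial_concentration=c0)


def gen_mm_rates(vmax: float, km: float, concentrations,
                 noise: NoiseModel, n_replicates: int = 1) -> MMKineticsDataset:
    """Michaelis-Menten rate data v = Vmax*C/(Km + C) with assay noise."""
    conc = np.asarray(concentrations, dtype=float)
    if vmax <= 0 or km <= 0:
        raise InvalidParameterError("vmax and km must be > 0")
    truth = vmax * conc / (km + conc)
    rng = np.random.default_rng(noise.seed)
    reps = np.vstack([noise.apply(truth, rng) for _ in range(n_replicates)])
    return MMKineticsDataset(substrate_concentrations=conc, rates=reps)


def gen_pk_observations(result, compound: str, sampling_times_h,
                        noise: NoiseModel) -> pd.DataFrame:
    """Sparse noisy plasma observations from a simulated truth profile.

    ``result`` is a :class:`~dabepbpk.engine.SimulationResult`; the truth
    curve is interpolated at the sparse sampling times (hours after the
    substrate dose), multiplied by log-normal error, and censored below
    the LLOQ (censored rows keep their time with conc = NaN and
    ``censored=True``).  Raises when every sample is censored.
    """
    t_obs = np.asarray(sampling_times_h, dtype=float)
    truth = np.interp(t_obs, result.times_after_dose, result.profile(compound))
    rng = np.random.default_rng(noise.seed)
    obs = noise.apply(truth, rng)
    censored = obs < noise.lloq
    if censored.all():
        raise InvalidDataError("all samples fell below the LLOQ")
    return pd.DataFrame({
        "time_h": t_obs,
        "compound": compound,
        "conc_ng_per_ml": np.where(censored, np.nan, obs),
        "censored": censored,
    })
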