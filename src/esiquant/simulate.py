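"""Synthetic LC/ESI/HRMS dilution-series generator with known ground truth.

Emulates the statistical structure that the quantification method relies
on, so calibration, descriptor construction, model training and evaluation
can be exercised without instrument data:

* response factors spanning several orders of magnitude (log10 RF drawn
  per polarity from Gaussians, defaults centred near 10^15.5 M^-1 with the
  positive-mode distribution skewed high and a low tail, matching a span
  of roughly 10^12-10^17.5 M^-1 across a few hundred compounds);
* dual-polarity detection at mobile-phase pH 2.7, 8.0 and 10.0, with only
  a fraction of compounds ionizing in negative mode;
* dilution series (1, 2, 4, 20, 40 for training standards; 1, 2, 10, 20,
  100 for test compounds) with multiplicative log-normal area noise and
  censoring below a limit-of-detection area threshold;
* latent lipophilicity driving retention time, and latent basicity/acidity
  driving both the pH-dependent retention-time shift and the polarity
  offsets of the response factor, so that the log positive/negative area
  ratio correlates with the positive-mode log RF and compounds shifting to
  longer retention at high pH tend to have higher positive-mode RFs.

Everything is reproducible from ``SimulationConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ValidationError
from .tables import (
    PROTON_MASS,
    SCAN_RANGE_MZ,
    VALID_PHS,
    ConditionKey,
    PeakRecord,
)


@dataclass(frozen=True, slots=True)
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults mirror the study conditions: five-dilution calibration series,
    standard concentrations 1.7e-6 to 2.4e-5 M, three mobile-phase pHs in
    both polarities, and a minimum detectable peak area of 1e4 counts.
    ``ph_trend_pos`` is the decrease of positive-mode log10 RF from pH 2.7
    to pH 10.0; ``rt_rf_coupling`` is the lipophilicity contribution to
    log10 RF (set to 0 to decorrelate retention time from RF).
    """

    n_compounds: int = 200
    seed: int = 0
    log_rf_mean_pos: float = 15.5
    log_rf_sd_pos: float = 1.2
    log_rf_mean_neg: float = 15.0
    log_rf_sd_neg: float = 1.0
    frac_neg_detectable: float = 0.5
    rt_range: tuple[float, float] = (2.0, 18.0)
    noise_cv: float = 0.1
    lod_area: float = 1.0e4
    dilution_factors_train: tuple[float, ...] = (1.0, 2.0, 4.0, 20.0, 40.0)
    dilution_factors_test: tuple[float, ...] = (1.0, 2.0, 10.0, 20.0, 100.0)
    conc_range_M: tuple[float, float] = (1.7e-6, 2.4e-5)
    ph_trend_pos: float = 0.5
    ph_trend_neg: float = 0.0
    rt_rf_coupling: float = 0.3
    basicity_coef: float = 0.6
    acidity_coef: float = 0.6
    rt_shift_scale_min: float = 1.5
    rt_jitter_sd: float = 0.05
    na_adduct_prob: float = 0.3

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValidationError("n_compounds must be >= 1")
        if not 0 <= self.frac_neg_detectable <= 1:
            raise ValidationError("frac_neg_detectable must lie in [0, 1]")
        if not 0 <= self.na_adduct_prob <= 1:
            raise ValidationError("na_adduct_prob must lie in [0, 1]")
        for name in ("log_rf_sd_pos", "log_rf_sd_neg"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("lod_area", "noise_cv", "rt_jitter_sd", "rt_rf_coupling",
                     "basicity_coef", "acidity_coef", "ph_trend_pos",
                     "ph_trend_neg", "rt_shift_scale_min"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        lo, hi = self.rt_range
        if not 0 < lo < hi:
            raise ValidationError("rt_range must satisfy 0 < min < max")
        if self.rt_shift_scale_min >= lo:
            raise ValidationError(
                "rt_shift_scale_min must be below rt_range minimum "
                "(retention times must stay positive)"
            )
        clo, chi = self.conc_range_M
        if not 0 < clo <= chi:
            raise ValidationError("conc_range_M must satisfy 0 < min <= max")
        if any(d < 1 for d in self.dilution_factors_train + self.dilution_factors_test):
            raise ValidationError("dilution factors must be >= 1")


@dataclass(frozen=True, slots=True)
class LatentCompoundProfile:
    """Ground truth for one simulated compound."""

    compound_id: str
    latent_lipophilicity: float
    latent_basicity: float
    latent_acidity: float
    true_log_rf: Mapping[ConditionKey, float]
    true_rt: Mapping[float, float]
    neutral_mass: float
    base_concentration_M: float
    na_adduct: bool


def _ph_fraction(ph: float) -> float:
    return (ph - VALID_PHS[0]) / (VALID_PHS[-1] - VALID_PHS[0])


def simulate_compounds(
    config: SimulationConfig, id_prefix: str = "cmp"
) -> list[LatentCompoundProfile]:
    """Draw ``config.n_compounds`` latent profiles, deterministically."""
    rng = np.random.default_rng(config.seed)
    n = config.n_compounds
    lip = rng.standard_normal(n)
    basicity = np.abs(rng.standard_normal(n))
    acidity = np.abs(rng.standard_normal(n))
    z_pos = rng.standard_normal(n)
    z_neg = rng.standard_normal(n)
    neg_detectable = rng.random(n) < config.frac_neg_detectable
    mass = np.clip(400.0 + 120.0 * lip + rng.normal(0.0, 60.0, n), 100.0, 900.0)
    log_c0 = rng.uniform(
        math.log10(config.conc_range_M[0]), math.log10(config.conc_range_M[1]), n
    )
    na_flags = rng.random(n) < config.na_adduct_prob

    rt_lo, rt_hi = config.rt_range
    width = len(str(max(n - 1, 1)))
    profiles: list[LatentCompoundProfile] = []
    for i in range(n):
        base_rt = rt_lo + (rt_hi - rt_lo) * norm.cdf(lip[i])
        shift_unit = config.rt_shift_scale_min * math.tanh(
            basicity[i] - acidity[i]
        )
        true_rt = {ph: base_rt + shift_unit * _ph_fraction(ph) for ph in VALID_PHS}
        log_rf: dict[ConditionKey, float] = {}
        for ph in VALID_PHS:
            log_rf[ConditionKey("positive", ph)] = (
                config.log_rf_mean_pos
                + config.log_rf_sd_pos * z_pos[i]
                + config.rt_rf_coupling * lip[i]
                + config.basicity_coef * basicity[i]
                - config.ph_trend_pos * _ph_fraction(ph)
            )
            if neg_detectable[i]:
                log_rf[ConditionKey("negative", ph)] = (
                    config.log_rf_mean_neg
                    + config.log_rf_sd_neg * z_neg[i]
                    + config.rt_rf_coupling * lip[i]
                    + config.acidity_coef * acidity[i]
                    - config.ph_trend_neg * _ph_fraction(ph)
                )
        profiles.append(
            LatentCompoundProfile(
                compound_id=f"{id_prefix}{i:0{width}d}",
                latent_lipophilicity=float(lip[i]),
                latent_basicity=float(basicity[i]),
                latent_acidity=float(acidity[i]),
                true_log_rf=log_rf,
                true_rt=true_rt,
                neutral_mass=float(mass[i]),
                base_concentration_M=float(10.0 ** log_c0[i]),
                na_adduct=bool(na_flags[i]),
            )
        )
    return profiles


def simulate_feature_table(
    profiles: Sequence[LatentCompoundProfile],
    config: SimulationConfig,
    dilution_factors: Sequence[float] | None = None,
    rng_stream: int = 1,
) -> tuple[list[PeakRecord], dict[tuple[str, float], float]]:
    """Realize a feature table and its standards (truth) concentrations.

    The expected area of a detected feature is concentration x 10^log RF;
    the realized area multiplies this by exp(N(0, noise_cv)). Realized
    areas below ``config.lod_area`` are emitted as not-detected records.
    Returns the peak records and the mapping (compound_id, dilution) ->
    molar concentration. ``rng_stream`` separates the noise of independent
    tables (e.g. training vs test realizations) under one seed.
    """
    if not profiles:
        raise ValidationError("profiles must be nonempty")
    dilutions = tuple(dilution_factors or config.dilution_factors_train)
    rng = np.random.default_rng([config.seed, rng_stream])
    records: list[PeakRecord] = []
    standards: dict[tuple[str, float], float] = {}
    for p in profiles:
        for cond in sorted(p.true_log_rf):
            ion_mz = p.neutral_mass + (
                PROTON_MASS if cond.mode == "positive" else -PROTON_MASS
            )
            ion_mz = float(np.clip(ion_mz, *SCAN_RANGE_MZ))
            for d in dilutions:
                conc = p.base_concentration_M / d
                standards[(p.compound_id, float(d))] = conc
                expected = conc * 10.0 ** p.true_log_rf[cond]
                noise = rng.normal(0.0, config.noise_cv) if config.noise_cv else 0.0
                jitter = (
                    rng.normal(0.0, config.rt_jitter_sd) if config.rt_jitter_sd else 0.0
                )
                area = expected * math.exp(noise)
                detected = area >= config.lod_area
                records.append(
                    PeakRecord(
                        compound_id=p.compound_id,
                        condition=cond,
                        dilution_factor=float(d),
                        area=area if detected else None,
                        rt=max(p.true_rt[cond.ph] + jitter, 1e-3) if detected else None,
                        mz_observed=ion_mz,
                        na_adduct=bool(
                            p.na_adduct
                            and detected
                            and cond.ph == 2.7
                            and cond.mode == "positive"
                        ),
                    )
                )
    return records, standards


def ground_truth_table(profiles: Sequence[LatentCompoundProfile]) -> pd.DataFrame:
    """Long-format truth: compound_id, mode, ph, true_log_rf."""
    rows = [
        {
            "compound_id": p.compound_id,
            "mode": cond.mode,
            "ph": cond.ph,
            "true_log_rf": p.true_log_rf[cond],
        }
        for p in profiles
        for cond in sorted(p.true_log_rf)
    ]
    return pd.DataFrame(rows, columns=["compound_id", "mode", "ph", "true_log_rf"])


def standards_frame(standards: Mapping[tuple[str, float], float]) -> pd.DataFrame:
    """Standards mapping as a CSV-ready frame."""
    rows = [
        {"compound_id": cid, "dilution_factor": d, "concentration_M": c}
        for (cid, d), c in sorted(standards.items())
    ]
    return pd.DataFrame(
        rows, columns=["compound_id", "dilution_factor", "concentration_M"]
    )
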