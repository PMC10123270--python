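"""Synthetic ocular-biometry cohort generator.

No individual-level data are deposited with the study this package
emulates, so this module is the test substrate: it generates per-eye
cohorts whose marginal moments, structural (covariate-adjusted)
regression coefficients, and simple-regression slopes match the published
summary statistics.

The generative model
--------------------
Exogenous draws: age ~ truncated normal, male ~ Bernoulli, CCT ~ normal
(mutually independent).  The corneal stress-strain index is linear in age
and gender::

    SSI = ssi_mean + a_age*(age - E[age]) + d_male*(male - p_male) + eps

where ``a_age`` and ``d_male`` are solved from the *marginal-slope
targets*: writing ``delta_x = cov(x, SSI) / var(SSI)`` for the
auxiliary-regression coefficient of covariate x on SSI,
omitted-variable-bias algebra makes the simple-regression slope of an
outcome on SSI equal its structural SSI coefficient plus
``sum_x beta_x * delta_x``.  Matching the published marginal slopes to
the published adjusted coefficients therefore fixes ``delta_male`` and
``delta_age`` analytically (no tuning).

The two structural equations are then::

    ALemm = i_emm + 0.27*male + 0.48*SSI + eps_emm
    dAL   = i_d   + 0.07*age + 0.23*male - 2.49*SSI + eps_d

with intercepts set so the generated means equal the published cohort
means, and residual SDs set so the generated SDs equal the published SDs
after subtracting explained variance.  The corneal radius is recovered by
inverting the emmetropia formula, ``AL = ALemm + dAL``, and SER is the
Morgan-implied refraction plus independent optometric noise.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field
from scipy.stats import truncnorm

from .morgan import (
    DEFAULT_CONSTANTS,
    MorganConstants,
    al_emmetropia,
    al_morgan,
    cr_from_al_emmetropia,
    implied_ser,
)
from .records import ALL_COLUMNS, empty_cohort, guard_mask

__all__ = [
    "CalibrationError",
    "EmmetropiaEquation",
    "IncrementEquation",
    "CrossCorrelation",
    "GeneratorConfig",
    "calibrate_generator",
    "generate_cohort",
    "load_config",
    "save_config",
]


class CalibrationError(ValueError):
    """Raised when the published moments admit no generating process."""


class EmmetropiaEquation(BaseModel):
    """Structural equation for emmetropic AL: covariate-adjusted Model 2
    coefficients (age and CCT terms are 0 at the printed precision)."""

    model_config = ConfigDict(extra="forbid")

    beta_male: float = 0.27
    beta_ssi: float = 0.48
    intercept: Optional[float] = None  # calibrated to the target mean
    residual_sd: Optional[float] = Field(default=None, ge=0)  # calibrated to the target SD


class IncrementEquation(BaseModel):
    """Structural equation for the axial increment dAL (Model 3 coefficients)."""

    model_config = ConfigDict(extra="forbid")

    beta_age: float = 0.07
    beta_male: float = 0.23
    beta_ssi: float = -2.49
    intercept: Optional[float] = None
    residual_sd: Optional[float] = Field(default=None, ge=0)


class CrossCorrelation(BaseModel):
    """Auxiliary-regression coefficients cov(x, SSI)/var(SSI) linking the
    confounders to SSI; solved from the marginal-slope targets when None."""

    model_config = ConfigDict(extra="forbid")

    delta_age: Optional[float] = None
    delta_male: Optional[float] = None


class GeneratorConfig(BaseModel):
    """Full specification of the synthetic cohort generator.

    Defaults are the published cohort's right-eye summary statistics and
    regression coefficients; ``None`` fields are solved by
    :func:`calibrate_generator`.
    """

    model_config = ConfigDict(extra="forbid")

    n: int = Field(default=267, ge=0)
    seed: int = 12345

    # exogenous marginals
    age_mean: float = 22.0
    age_sd: float = Field(default=8.0, ge=0)
    age_bounds: tuple[float, float] = (6.0, 60.0)
    p_male: float = Field(default=0.46, ge=0.0, le=1.0)
    cct_mean: float = 544.0
    cct_sd: float = Field(default=34.0, ge=0)
    ssi_mean: float = 0.82
    ssi_sd: float = Field(default=0.15, ge=0)

    # structural equations (covariate-adjusted coefficients)
    emmetropia: EmmetropiaEquation = EmmetropiaEquation()
    increment: IncrementEquation = IncrementEquation()
    cross: CrossCorrelation = CrossCorrelation()

    # marginal (simple-regression) slope targets on SSI
    slope_al: float = -2.04
    slope_emm: float = 0.561
    slope_delta: float = -2.6

    # moment targets for the two structural outcomes
    emm_mean: float = 23.64
    emm_sd: float = Field(default=0.50, ge=0)
    delta_mean: float = 2.38
    delta_sd: float = Field(default=1.35, ge=0)

    # refraction noise (D) added to the Morgan-implied SER
    ser_noise_sd: float = Field(default=1.4, ge=0)

    # optional paired-eye mode: OS duplicates the structural draw + noise
    paired: bool = False
    paired_emm_sd: float = Field(default=0.10, ge=0)
    paired_delta_sd: float = Field(default=0.20, ge=0)

    max_redraws: int = Field(default=100, ge=1)

    def age_moments(self) -> tuple[float, float]:
        """Mean and variance of the truncated-normal age distribution."""
        if self.age_sd == 0:
            return self.age_mean, 0.0
        a = (self.age_bounds[0] - self.age_mean) / self.age_sd
        b = (self.age_bounds[1] - self.age_mean) / self.age_sd
        dist = truncnorm(a, b, loc=self.age_mean, scale=self.age_sd)
        return float(dist.mean()), float(dist.var())


def calibrate_generator(config: Optional[GeneratorConfig] = None, **overrides) -> GeneratorConfig:
    """Solve the free generator parameters from the published summaries.

    Fills, in order: (i) ``delta_male`` from the emmetropia marginal
    slope, (ii) ``delta_age`` from the increment marginal slope,
    (iii) the two structural intercepts from the target means, and
    (iv) the two structural residual SDs from the target SDs after
    subtracting explained variance.  Raises :class:`CalibrationError`
    when a residual variance goes negative or an implied correlation
    leaves (-1, 1).
    """
    if config is None:
        config = GeneratorConfig(**overrides)
    elif overrides:
        config = config.model_copy(update=overrides)

    cfg = config.model_copy(deep=True)
    emm, inc, cross = cfg.emmetropia, cfg.increment, cfg.cross

    age_mean, age_var = cfg.age_moments()
    ssi_var = cfg.ssi_sd**2
    pq = cfg.p_male * (1.0 - cfg.p_male)

    # (i) delta_male: marginal slope of ALemm on SSI = beta_ssi + beta_male*delta_male
    if cross.delta_male is None:
        if emm.beta_male == 0:
            if not math.isclose(cfg.slope_emm, emm.beta_ssi, abs_tol=1e-12):
                raise CalibrationError(
                    "emmetropia equation has no gender term to absorb the "
                    f"marginal-adjusted slope gap {cfg.slope_emm - emm.beta_ssi}"
                )
            cross.delta_male = 0.0
        else:
            cross.delta_male = (cfg.slope_emm - emm.beta_ssi) / emm.beta_male

    # (ii) delta_age: marginal slope of dAL on SSI =
    #      beta_ssi + beta_age*delta_age + beta_male*delta_male
    if cross.delta_age is None:
        gap = cfg.slope_delta - inc.beta_ssi - inc.beta_male * cross.delta_male
        if inc.beta_age == 0:
            if not math.isclose(gap, 0.0, abs_tol=1e-12):
                raise CalibrationError(
                    f"increment equation has no age term to absorb the slope gap {gap}"
                )
            cross.delta_age = 0.0
        else:
            cross.delta_age = gap / inc.beta_age

    # feasibility of the SSI auxiliary structure
    if ssi_var > 0:
        if age_var > 0:
            corr_age = cross.delta_age * math.sqrt(ssi_var / age_var)
            if abs(corr_age) >= 1:
                raise CalibrationError(f"implied corr(age, SSI) = {corr_age:.3f} is outside (-1, 1)")
        elif cross.delta_age != 0:
            raise CalibrationError("delta_age != 0 requires age variance > 0")
        if pq > 0:
            corr_male = cross.delta_male * math.sqrt(ssi_var / pq)
            if abs(corr_male) >= 1:
                raise CalibrationError(
                    f"implied corr(male, SSI) = {corr_male:.3f} is outside (-1, 1)"
                )
        elif cross.delta_male != 0:
            raise CalibrationError("delta_male != 0 requires 0 < p_male < 1")
        a_age = cross.delta_age * ssi_var / age_var if age_var > 0 else 0.0
        d_male = cross.delta_male * ssi_var / pq if pq > 0 else 0.0
        eps_var = ssi_var - a_age**2 * age_var - d_male**2 * pq
        if eps_var < 0:
            raise CalibrationError(
                f"SSI residual variance is negative ({eps_var:.3e}): the cross-"
                "correlations explain more variance than the target SSI SD allows"
            )

    cov_age_ssi = cross.delta_age * ssi_var
    cov_male_ssi = cross.delta_male * ssi_var

    # (iii) intercepts from target means
    if emm.intercept is None:
        emm.intercept = cfg.emm_mean - emm.beta_male * cfg.p_male - emm.beta_ssi * cfg.ssi_mean
    if inc.intercept is None:
        inc.intercept = (
            cfg.delta_mean
            - inc.beta_age * age_mean
            - inc.beta_male * cfg.p_male
            - inc.beta_ssi * cfg.ssi_mean
        )

    # (iv) residual SDs from target SDs minus explained variance
    if emm.residual_sd is None:
        explained = (
            emm.beta_male**2 * pq
            + emm.beta_ssi**2 * ssi_var
            + 2 * emm.beta_male * emm.beta_ssi * cov_male_ssi
        )
        resid_var = cfg.emm_sd**2 - explained
        if resid_var < 0:
            raise CalibrationError(
                f"emmetropic-AL residual variance is negative ({resid_var:.3e}); "
                f"explained variance {explained:.3e} exceeds the target SD {cfg.emm_sd}"
            )
        emm.residual_sd = math.sqrt(resid_var)
    if inc.residual_sd is None:
        explained = (
            inc.beta_age**2 * age_var
            + inc.beta_male**2 * pq
            + inc.beta_ssi**2 * ssi_var
            + 2 * inc.beta_age * inc.beta_ssi * cov_age_ssi
            + 2 * inc.beta_male * inc.beta_ssi * cov_male_ssi
        )
        resid_var = cfg.delta_sd**2 - explained
        if resid_var < 0:
            raise CalibrationError(
                f"axial-increment residual variance is negative ({resid_var:.3e}); "
                f"explained variance {explained:.3e} exceeds the target SD {cfg.delta_sd}"
            )
        inc.residual_sd = math.sqrt(resid_var)

    return cfg


def _draw_block(
    cfg: GeneratorConfig, n: int, rng: np.random.Generator, constants: MorganConstants
) -> pd.DataFrame:
    """Draw n candidate records (vectorised); guards not yet applied."""
    age_mean_t, age_var_t = cfg.age_moments()
    if cfg.age_sd > 0:
        a = (cfg.age_bounds[0] - cfg.age_mean) / cfg.age_sd
        b = (cfg.age_bounds[1] - cfg.age_mean) / cfg.age_sd
        age = truncnorm.rvs(a, b, loc=cfg.age_mean, scale=cfg.age_sd, size=n, random_state=rng)
    else:
        age = np.full(n, cfg.age_mean)
    male = (rng.random(n) < cfg.p_male).astype(float)
    cct = rng.normal(cfg.cct_mean, cfg.cct_sd, size=n)

    ssi_var = cfg.ssi_sd**2
    pq = cfg.p_male * (1.0 - cfg.p_male)
    a_age = cfg.cross.delta_age * ssi_var / age_var_t if age_var_t > 0 else 0.0
    d_male = cfg.cross.delta_male * ssi_var / pq if pq > 0 else 0.0
    eps_sd = math.sqrt(max(ssi_var - a_age**2 * age_var_t - d_male**2 * pq, 0.0))
    ssi = (
        cfg.ssi_mean
        + a_age * (age - age_mean_t)
        + d_male * (male - cfg.p_male)
        + rng.normal(0.0, eps_sd, size=n)
    )

    emm, inc = cfg.emmetropia, cfg.increment
    al_emm = (
        emm.intercept
        + emm.beta_male * male
        + emm.beta_ssi * ssi
        + rng.normal(0.0, emm.residual_sd, size=n)
    )
    d_al = (
        inc.intercept
        + inc.beta_age * age
        + inc.beta_male * male
        + inc.beta_ssi * ssi
        + rng.normal(0.0, inc.residual_sd, size=n)
    )
    ser_noise = rng.normal(0.0, cfg.ser_noise_sd, size=n)

    # Invert the emmetropia formula for CR; out-of-domain draws are marked
    # invalid (NaN) and redrawn by the guard loop.
    with np.errstate(divide="ignore", invalid="ignore"):
        u = 1.0 / al_emm - constants.c
        cr = np.where((al_emm > 0) & (u > 0), constants.a / np.maximum(u, 1e-12), np.nan)
    al = al_emm + d_al
    valid = np.isfinite(cr) & (al > 0) & (cr > 0)
    ser = np.full(n, np.nan)
    ser[valid] = implied_ser(al[valid], cr[valid], constants) + ser_noise[valid]

    return pd.DataFrame(
        {
            "age": age,
            "gender": np.where(male > 0, "male", "female"),
            "ser_d": ser,
            "ssi": ssi,
            "cct_um": cct,
            "cr_mm": cr,
            "al_mm": al,
        }
    )


def generate_cohort(
    config: GeneratorConfig, constants: MorganConstants = DEFAULT_CONSTANTS
) -> pd.DataFrame:
    """Generate a synthetic per-eye cohort as a DataFrame.

    Deterministic for a given ``config.seed``.  Records violating the
    physiological guards are redrawn (up to ``config.max_redraws``
    rounds); the output always passes every guard and has all derived
    fields populated.

    In paired mode each subject contributes an OD and an OS row; the OS
    row re-uses the subject's structural draw with small between-eye
    noise on the two structural outcomes.
    """
    cfg = calibrate_generator(config)
    rng = np.random.default_rng(cfg.seed)

    if cfg.n == 0:
        return empty_cohort()

    block = _draw_block(cfg, cfg.n, rng, constants)
    ok = guard_mask(block) & block.notna().all(axis=1)
    rounds = 0
    while not ok.all():
        rounds += 1
        if rounds > cfg.max_redraws:
            raise RuntimeError(
                f"{(~ok).sum()} records still violate physiological guards "
                f"after {cfg.max_redraws} redraw rounds; check the config"
            )
        redraw = _draw_block(cfg, int((~ok).sum()), rng, constants)
        block.loc[~ok, redraw.columns] = redraw.to_numpy()
        ok = guard_mask(block) & block.notna().all(axis=1)

    block.insert(0, "subject_id", [f"S{i + 1:05d}" for i in range(cfg.n)])
    block.insert(1, "eye", "OD")

    if cfg.paired:
        os_block = block.copy()
        os_block["eye"] = "OS"
        emm_od = al_emmetropia(block["cr_mm"].to_numpy(), constants)
        d_od = block["al_mm"].to_numpy() - emm_od
        emm_os = emm_od + rng.normal(0.0, cfg.paired_emm_sd, size=cfg.n)
        d_os = d_od + rng.normal(0.0, cfg.paired_delta_sd, size=cfg.n)
        os_block["cr_mm"] = cr_from_al_emmetropia(np.maximum(emm_os, 16.0), constants)
        os_block["al_mm"] = emm_os + d_os
        os_block["ser_d"] = implied_ser(
            os_block["al_mm"].to_numpy(), os_block["cr_mm"].to_numpy(), constants
        ) + rng.normal(0.0, cfg.ser_noise_sd, size=cfg.n)
        block = (
            pd.concat([block, os_block], ignore_index=True)
            .sort_values(["subject_id", "eye"], kind="stable")
            .reset_index(drop=True)
        )

    block["al_emmetropia_mm"] = al_emmetropia(block["cr_mm"].to_numpy(), constants)
    block["al_morgan_mm"] = al_morgan(
        block["cr_mm"].to_numpy(), block["ser_d"].to_numpy(), constants
    )
    block["delta_al_mm"] = block["al_mm"] - block["al_emmetropia_mm"]
    return block[ALL_COLUMNS]


def load_config(path: Union[str, Path]) -> GeneratorConfig:
    """Load a GeneratorConfig from YAML or JSON; unknown keys are rejected."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)  # YAML is a superset of JSON
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping, got {type(data).__name__}")
    return GeneratorConfig(**data)


def save_config(config: GeneratorConfig, path: Union[str, Path]) -> Path:
    """Write a GeneratorConfig as YAML (round-trips through load_config)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=True)
    return path
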