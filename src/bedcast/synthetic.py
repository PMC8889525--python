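"""Synthetic daily census generator.

Emulates the statistical structure of a ~350-bed tertiary hospital's daily
inpatient bed demand: a base occupancy level, an additive weekly profile
with a mid-week high and a weekend trough (fewer scheduled surgeries and
discharging physicians on weekends), stationary autoregressive noise, and
covariate censuses (medicine, surgical, midnight) that co-move with demand.
Optional regime switching (persistent shifts of the mean level, e.g. a
seasonal surge) produces the multimodal demand histograms that make
clustering into K > 1 demand groups meaningful.

Every series is reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .census import ALL_DAYS, COVARIATE_ROLES, CensusSeries


class SyntheticConfigError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class Regime:
    """A persistent demand regime: a level shift with its own weekly dynamics.

    ``mean_duration`` is the expected sojourn, in days, of a geometric
    duration distribution (minimum 1 day); regimes cycle in list order.
    ``profile_gain`` scales the weekday profile while the regime is active —
    a surge regime driven by elective surgical volume both raises the level
    and amplifies the mid-week/weekend swing, so the two regimes differ in
    their lag dynamics (feature signature), not just in mean.
    """

    shift: float
    mean_duration: float
    profile_gain: float = 1.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic census generator.

    Defaults describe a ~350-bed hospital: level 340 beds, a weekly profile
    peaking mid-week (+15) and dipping on the weekend (-25), AR(2) noise
    (coefficients 0.5 and 0.2, innovation sd 8 beds) making demand lags 1-3
    and the weekly lag informative, and covariates that are noisy linear
    maps of demand.
    """

    n_days: int = 1095
    base_level: float = 340.0
    #: additive offsets Monday..Sunday, beds
    weekday_profile: tuple[float, ...] = (5.0, 12.0, 15.0, 12.0, 0.0, -22.0, -25.0)
    ar_coefficients: tuple[float, ...] = (0.5, 0.2)
    noise_sd: float = 8.0
    #: innovation-sd multiplier on Saturdays/Sundays.  Weekend census moves
    #: little and predictably (no elective surgery, low admission/discharge
    #: turnover), so weekend shocks are smaller than weekday ones.
    weekend_noise_scale: float = 0.5
    regimes: tuple[Regime, ...] | None = None
    #: role -> (slope on demand, additive noise sd)
    covariate_loadings: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "medicine_census": (0.45, 4.0),
            "surgical_census": (0.25, 3.0),
            "midnight_census": (0.95, 3.0),
        }
    )
    start_date: str = "2015-01-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 30:
            raise SyntheticConfigError("n_days must be >= 30")
        if len(self.weekday_profile) != 7:
            raise SyntheticConfigError("weekday_profile needs 7 offsets (Mon..Sun)")
        prof = np.asarray(self.weekday_profile)
        if int(np.argmax(prof)) not in (1, 2, 3):
            raise SyntheticConfigError(
                "weekday_profile must peak on Tue/Wed/Thu"
            )
        if int(np.argmin(prof)) not in (5, 6):
            raise SyntheticConfigError(
                "weekday_profile must trough on Sat/Sun"
            )
        if self.noise_sd < 0:
            raise SyntheticConfigError("noise_sd must be >= 0")
        if not 0 <= self.weekend_noise_scale <= 1:
            raise SyntheticConfigError(
                "weekend_noise_scale must be in [0, 1]"
            )
        for role in self.covariate_loadings:
            if role not in COVARIATE_ROLES:
                raise SyntheticConfigError(f"unknown covariate role {role!r}")
        phi = np.asarray(self.ar_coefficients, dtype=float)
        if len(phi):
            # stationary iff all roots of 1 - phi_1 z - ... - phi_p z^p lie
            # outside the unit circle
            roots = np.roots(np.r_[-phi[::-1], 1.0])
            if np.any(np.abs(roots) <= 1.0 + 1e-9):
                raise SyntheticConfigError(
                    f"AR coefficients {tuple(phi)} are not stationary"
                )


def _ar_noise(rng: np.random.Generator, n: int, phi: np.ndarray,
              sd_by_day: np.ndarray, burn: int = 200) -> np.ndarray:
    """AR(p) noise with per-day innovation sd (index-aligned with the series;
    the burn-in continues the weekly sd pattern backwards)."""
    p = len(phi)
    if np.all(sd_by_day == 0):
        return np.zeros(n)
    sd_full = np.empty(n + burn)
    sd_full[burn:] = sd_by_day
    sd_full[:burn] = sd_by_day[np.arange(-burn, 0) % n]
    eps = rng.normal(0.0, 1.0, size=n + burn) * sd_full
    x = np.zeros(n + burn)
    for t in range(n + burn):
        ar = sum(phi[i] * x[t - 1 - i] for i in range(min(p, t)))
        x[t] = ar + eps[t]
    return x[burn:]


def _regime_path(rng: np.random.Generator, n: int,
                 regimes: Sequence[Regime]) -> tuple[np.ndarray, np.ndarray]:
    """Per-day (level shift, profile gain) from cycling geometric sojourns."""
    shift = np.empty(n)
    gain = np.empty(n)
    i = 0
    t = 0
    while t < n:
        reg = regimes[i % len(regimes)]
        dur = int(rng.geometric(min(1.0, 1.0 / max(reg.mean_duration, 1.0))))
        dur = max(dur, 1)
        shift[t : t + dur] = reg.shift
        gain[t : t + dur] = reg.profile_gain
        t += dur
        i += 1
    return shift, gain


def generate(config: SyntheticConfig) -> CensusSeries:
    """Generate a daily census series from the configuration.

    Demand on day ``d`` is ``round(base + shift(d) + gain(d) *
    profile[weekday(d)] + AR-noise(d))`` floored at 0, where shift/gain come
    from the active regime (0/1 with no regimes); each covariate is its
    loading times demand plus independent Gaussian noise, rounded and
    floored at 0.
    """
    rng = np.random.default_rng(config.seed)
    dates = pd.date_range(config.start_date, periods=config.n_days, freq="D")
    profile = np.asarray(config.weekday_profile)[dates.dayofweek]
    sd_by_day = np.where(
        dates.dayofweek >= 5,
        config.noise_sd * config.weekend_noise_scale,
        config.noise_sd,
    ).astype(float)
    noise = _ar_noise(
        rng, config.n_days, np.asarray(config.ar_coefficients, dtype=float),
        sd_by_day,
    )
    if config.regimes:
        shift, gain = _regime_path(rng, config.n_days, config.regimes)
    else:
        shift = np.zeros(config.n_days)
        gain = np.ones(config.n_days)
    demand = np.round(config.base_level + shift + gain * profile + noise)
    demand = np.clip(demand, 0, None).astype(np.int64)

    data: dict[str, np.ndarray] = {"demand": demand}
    for role in COVARIATE_ROLES:
        if role not in config.covariate_loadings:
            continue
        slope, sd = config.covariate_loadings[role]
        vals = np.round(slope * demand + rng.normal(0.0, sd, config.n_days))
        data[role] = np.clip(vals, 0, None).astype(np.int64)

    return CensusSeries(pd.DataFrame(data, index=dates), ALL_DAYS)


# --------------------------------------------------------------------------
# presets

def _load_presets() -> dict:
    text = resources.files("bedcast").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def available_presets() -> list[str]:
    return sorted(_load_presets())


def preset(name: str, **overrides) -> SyntheticConfig:
    """Build a named preset configuration, with keyword overrides.

    ``tertiary_350``: the plain weekly-seasonal hospital series.
    ``regime_switching``: adds two alternating demand regimes (a baseline
    and a +60-bed surge, expected duration 60 days each) so the demand
    histogram is bimodal and cluster-local regression has structure to
    exploit.
    """
    presets = _load_presets()
    if name not in presets:
        raise SyntheticConfigError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        )
    spec = dict(presets[name])
    regimes = spec.pop("regimes", None)
    if regimes is not None:
        spec["regimes"] = tuple(Regime(**r) for r in regimes)
    if "weekday_profile" in spec:
        spec["weekday_profile"] = tuple(spec["weekday_profile"])
    if "ar_coefficients" in spec:
        spec["ar_coefficients"] = tuple(spec["ar_coefficients"])
    if "covariate_loadings" in spec:
        spec["covariate_loadings"] = {
            k: tuple(v) for k, v in spec["covariate_loadings"].items()
        }
    spec.update(overrides)
    return SyntheticConfig(**spec)
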