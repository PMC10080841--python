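"""Synthetic daily admission panels with known ground-truth structure.

Real hospital-admission series of the kind this package targets (daily
cerebrovascular admissions together with city-level air-quality and
meteorological monitoring data) are almost always access-restricted.  This
module generates panels with the same shape and statistical character —
a rising multi-year trend, annual and weekly seasonality, holiday dips,
short-term lagged environmental effects and overdispersed counts — so that
every downstream stage (feature construction, stacking, re-weighting,
explanation) can be exercised and tested against a known generating process.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "ENV_COLUMNS",
    "GENERATED_ENV_COLUMNS",
    "PANEL_COLUMNS",
    "GeneratorConfig",
    "default_holidays",
    "generate_panel",
    "inject_missing",
    "panel_summary",
    "validate_panel",
]

#: Environmental columns of a panel, in canonical CSV order.
ENV_COLUMNS = ["pm25", "pm10", "pmc", "so2", "no2", "co", "o3", "aqi", "tem", "rh"]

#: Columns drawn directly by the generator.  ``pm10 = pm25 + pmc`` and ``aqi``
#: is a deterministic function of the pollutants, so neither is drawn.
GENERATED_ENV_COLUMNS = ["pm25", "pmc", "so2", "no2", "co", "o3", "tem", "rh"]

PANEL_COLUMNS = ["date", "ha_count"] + ENV_COLUMNS

# Reference scales used by the synthetic air-quality index:
# aqi = 100 * max_P(concentration_P / ref_P).  The scales are loosely based on
# the Chinese AQI level-2 (moderate) breakpoints so that typical urban
# concentrations yield indices near 100; the index is a documented monotone
# proxy, not a regulatory computation.
AQI_REFERENCE = {
    "pm25": 75.0,   # µg/m³
    "pm10": 150.0,  # µg/m³
    "so2": 150.0,   # µg/m³
    "no2": 80.0,    # µg/m³
    "co": 4.0,      # mg/m³
    "o3": 160.0,    # µg/m³
}

# Seasonal structure of each generated environmental series: fraction of unit
# variance carried by the annual harmonic, day-of-year of the seasonal peak,
# and lag-1 autocorrelation of the residual noise.
_ENV_SEASONALITY = {
    #        amp    peak  rho
    "pm25": (0.80, 15.0, 0.70),
    "pmc":  (0.70, 15.0, 0.65),
    "so2":  (0.70, 20.0, 0.70),
    "no2":  (0.60, 10.0, 0.70),
    "co":   (0.70, 20.0, 0.70),
    "o3":   (1.00, 190.0, 0.60),
    "tem":  (0.90, 200.0, 0.70),
    "rh":   (0.40, 250.0, 0.50),
}

_DEFAULT_ENV_MEANS = {
    "pm25": 57.9, "pmc": 37.8, "so2": 12.7, "no2": 53.9,
    "co": 1.0, "o3": 96.6, "tem": 16.9, "rh": 80.5,
}
_DEFAULT_ENV_SDS = {
    "pm25": 40.6, "pmc": 25.6, "so2": 5.5, "no2": 17.7,
    "co": 0.4, "o3": 54.6, "tem": 7.3, "rh": 9.2,
}

# Default short-term (lags 1..6) effects of standardized environmental series
# on the log intensity of admissions.  High temperature and high gaseous /
# particulate pollution raise the expected count; humidity has a weak
# protective effect.  Magnitudes are per standard deviation of the series.
_DEFAULT_ENV_EFFECTS = {
    "tem": [0.09, 0.07, 0.05, 0.03, 0.02, 0.02],
    "o3": [0.06, 0.03, 0.02, 0.01, 0.0, 0.0],
    "pm25": [0.03, 0.02, 0.02, 0.01, 0.0, 0.0],
    "co": [0.02, 0.01, 0.0, 0.0, 0.0, 0.0],
    "no2": [0.01, 0.01, 0.0, 0.0, 0.0, 0.0],
    "rh": [-0.02, -0.01, 0.0, 0.0, 0.0, 0.0],
}

# Weekly multiplicative effects on the log scale, Monday..Sunday.  Elective
# admissions drop sharply at weekends.
_DEFAULT_WEEKLY = [0.06, 0.08, 0.07, 0.05, 0.03, -0.12, -0.28]


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic daily-panel generating process.

    The defaults are calibrated so that a four-year (1461-day) panel has a
    count mean near 70 and standard deviation near 35 — the scale of daily
    cerebrovascular admissions in a large city — with a rising trend, annual
    and weekly seasonality, holiday dips, and overdispersion relative to
    Poisson.
    """

    start_date: date = date(2015, 1, 1)
    n_days: int = 1461
    #: expected count at the first day, before seasonal/holiday effects
    baseline_level: float = 51.5
    #: multiplicative growth per year, log scale
    yearly_trend: float = 0.14
    #: amplitude of the annual harmonic, log scale
    annual_amplitude: float = 0.55
    #: day-of-year at which the annual harmonic peaks (winter admissions peak)
    annual_peak_doy: float = 15.0
    #: Monday..Sunday additive effects, log scale
    weekly_effects: tuple[float, ...] = tuple(_DEFAULT_WEEKLY)
    #: additive effect of a holiday, log scale; deep dips emulate week-long
    #: hospital shutdown periods around major holidays
    holiday_effect: float = -0.70
    #: variable -> per-lag coefficients (lags 1..L), log scale per SD
    env_effect_coeffs: dict[str, list[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_ENV_EFFECTS.items()}
    )
    #: "poisson", "deterministic" (counts = round(intensity)), or a positive
    #: negative-binomial dispersion (smaller = more overdispersed)
    dispersion: float | str = 45.0
    env_means: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_ENV_MEANS))
    env_sds: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_ENV_SDS))
    #: disable the autocorrelated noise of environmental series (seasonal only)
    env_noise: bool = True
    missing_rate: float = 0.0
    holidays: frozenset[date] | None = None
    seed: int = 42

    @property
    def max_lag(self) -> int:
        lags = [len(v) for v in self.env_effect_coeffs.values()]
        return max(lags) if lags else 0

    def validate(self) -> None:
        if self.n_days < 2 * max(self.max_lag, 1) + 10:
            raise ConfigurationError(
                f"n_days={self.n_days} too small; need at least 2*L+10 days"
            )
        if self.baseline_level <= 0:
            raise ConfigurationError("baseline_level must be positive")
        if len(self.weekly_effects) != 7:
            raise ConfigurationError("weekly_effects must have 7 entries (Mon..Sun)")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if isinstance(self.dispersion, str):
            if self.dispersion not in ("poisson", "deterministic"):
                raise ConfigurationError(
                    "dispersion must be positive, 'poisson' or 'deterministic'"
                )
        elif self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        for name in self.env_effect_coeffs:
            if name not in GENERATED_ENV_COLUMNS:
                raise ConfigurationError(f"unknown environmental variable {name!r}")
        for table, label in ((self.env_means, "env_means"), (self.env_sds, "env_sds")):
            for name in GENERATED_ENV_COLUMNS:
                if name not in table:
                    raise ConfigurationError(f"{label} missing entry for {name!r}")
        if any(sd <= 0 for sd in self.env_sds.values()):
            raise ConfigurationError("env_sds must be positive")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


def default_holidays(years: range | list[int], seed: int = 0) -> frozenset[date]:
    """A synthetic recurring holiday calendar.

    Fixed blocks: Jan 1–3 (New Year) and Oct 1–7 (National Day week), plus a
    movable seven-day block per year whose start is drawn deterministically
    from late January to mid-February (a stand-in for the lunar Spring
    Festival week, which shifts from year to year).
    """
    rng = np.random.default_rng(seed)
    days: set[date] = set()
    for year in years:
        for d in range(1, 4):
            days.add(date(year, 1, d))
        for d in range(1, 8):
            days.add(date(year, 10, d))
        start = date(year, 1, 21) + timedelta(days=int(rng.integers(0, 26)))
        days.update(start + timedelta(days=d) for d in range(7))
    return frozenset(days)


def _env_series(config: GeneratorConfig, rng: np.random.Generator,
                doy: np.ndarray) -> dict[str, np.ndarray]:
    """Draw the eight generated environmental series on their natural scale."""
    out = {}
    for name in GENERATED_ENV_COLUMNS:
        amp, peak, rho = _ENV_SEASONALITY[name]
        seasonal = amp * np.cos(2 * np.pi * (doy - peak) / 365.25)
        noise_var = max(1.0 - amp * amp / 2.0, 0.05)
        if config.env_noise:
            innov_sd = np.sqrt(noise_var * (1 - rho * rho))
            eps = rng.normal(0.0, innov_sd, size=len(doy))
            noise = np.empty(len(doy))
            acc = rng.normal(0.0, np.sqrt(noise_var))
            for t in range(len(doy)):
                acc = rho * acc + eps[t]
                noise[t] = acc
        else:
            noise = np.zeros(len(doy))
        z = seasonal + noise
        values = config.env_means[name] + config.env_sds[name] * z
        if name == "rh":
            values = np.clip(values, 5.0, 100.0)
        elif name != "tem":  # concentrations cannot go negative
            values = np.maximum(values, 0.05 * config.env_sds[name])
        out[name] = values
    return out


def compute_aqi(env: dict[str, np.ndarray] | pd.DataFrame) -> np.ndarray:
    """Synthetic air-quality index: 100 x the worst pollutant/reference ratio.

    Monotone in every pollutant and deterministic; a proxy for the composite
    regulatory index, which is defined only up to its pollutant sub-indices.
    """
    ratios = [np.asarray(env[name], dtype=float) / ref
              for name, ref in AQI_REFERENCE.items()]
    return 100.0 * np.max(np.vstack(ratios), axis=0)


def generate_panel(config: GeneratorConfig,
                   return_truth: bool = False) -> pd.DataFrame | tuple[pd.DataFrame, dict]:
    """Generate a daily panel of admission counts and environmental series.

    The count intensity is log-linear::

        log mu(t) = log(baseline) + trend*years(t) + annual harmonic
                    + weekly effect + holiday effect
                    + sum_P sum_{x=1..L} coeff[P][x] * z_P(t - x)

    where ``z_P`` is the standardized environmental series.  Counts are drawn
    Poisson or negative-binomial around ``mu``; ``dispersion="deterministic"``
    returns ``round(mu)`` for exact structural tests.

    With ``return_truth=True`` also returns a dict with the log-intensity,
    the holiday mask and the standardized environmental series, enabling
    ground-truth checks downstream.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_days
    dates = pd.date_range(config.start_date, periods=n, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    years_elapsed = np.arange(n) / 365.25

    env = _env_series(config, rng, doy)
    z = {name: (env[name] - config.env_means[name]) / config.env_sds[name]
         for name in GENERATED_ENV_COLUMNS}

    holidays = config.holidays
    if holidays is None:
        holidays = default_holidays(
            range(dates[0].year, dates[-1].year + 1), seed=config.seed)
    hol_mask = np.array([d.date() in holidays for d in dates])

    log_mu = (
        np.log(config.baseline_level)
        + config.yearly_trend * years_elapsed
        + config.annual_amplitude
        * np.cos(2 * np.pi * (doy - config.annual_peak_doy) / 365.25)
        + np.asarray(config.weekly_effects)[dates.dayofweek.to_numpy()]
        + config.holiday_effect * hol_mask
    )
    for name, coeffs in config.env_effect_coeffs.items():
        series = z[name]
        for lag, c in enumerate(coeffs, start=1):
            if c == 0.0:
                continue
            lagged = np.empty(n)
            lagged[:lag] = 0.0  # no history before the panel start
            lagged[lag:] = series[:-lag]
            log_mu += c * lagged

    mu = np.exp(log_mu)
    if config.dispersion == "deterministic":
        counts = np.round(mu).astype(np.int64)
    elif config.dispersion == "poisson":
        counts = rng.poisson(mu).astype(np.int64)
    else:
        theta = float(config.dispersion)
        # NB as a gamma-Poisson mixture: shape theta, mean mu
        lam = rng.gamma(theta, mu / theta)
        counts = rng.poisson(lam).astype(np.int64)

    panel = pd.DataFrame({"date": dates, "ha_count": counts})
    panel["pm25"] = env["pm25"]
    panel["pmc"] = env["pmc"]
    panel["pm10"] = env["pm25"] + env["pmc"]
    for name in ("so2", "no2", "co", "o3"):
        panel[name] = env[name]
    panel["aqi"] = compute_aqi(panel)
    panel["tem"] = env["tem"]
    panel["rh"] = env["rh"]
    panel = panel[PANEL_COLUMNS]

    if config.missing_rate > 0:
        panel = inject_missing(panel, config.missing_rate, seed=config.seed)

    if return_truth:
        truth = {"log_intensity": log_mu, "intensity": mu,
                 "holiday_mask": hol_mask, "standardized_env": z,
                 "holidays": holidays}
        return panel, truth
    return panel


def inject_missing(panel: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Blank all environmental cells on ``round(rate * n_days)`` random days.

    Missingness is day-level across the environmental columns jointly —
    monitoring outages knock out the whole daily record — and never touches
    ``date`` or ``ha_count``.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    panel = panel.copy()
    n_missing = int(round(rate * len(panel)))
    if n_missing == 0:
        return panel
    rng = np.random.default_rng(seed)
    rows = rng.choice(len(panel), size=n_missing, replace=False)
    panel.iloc[rows, [panel.columns.get_loc(c) for c in ENV_COLUMNS]] = np.nan
    return panel


def validate_panel(panel: pd.DataFrame) -> None:
    """Check the structural invariants of a daily panel; raise on violation."""
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel lacks columns: {missing}")
    dates = pd.to_datetime(panel["date"])
    deltas = dates.diff().dropna()
    if not (deltas == pd.Timedelta(days=1)).all():
        raise ValueError("panel dates must increase by exactly one day")
    if panel["ha_count"].isna().any():
        raise ValueError("ha_count must have no missing values")
    if (panel["ha_count"] < 0).any():
        raise ValueError("ha_count must be non-negative")
    both = panel[["pm25", "pm10", "pmc"]].dropna()
    if not np.allclose(both["pm10"] - both["pm25"], both["pmc"], atol=1e-9):
        raise ValueError("PMc must equal PM10 - PM2.5 wherever both present")


def panel_summary(panel: pd.DataFrame) -> pd.DataFrame:
    """Descriptive statistics per column: mean, SD, min, quartiles, max.

    SD is the sample standard deviation (ddof=1); percentiles use the
    linear-interpolation rule, matching pandas' default ``describe``.
    """
    if len(panel) == 0:
        raise ValueError("panel is empty")
    numeric = panel.drop(columns=["date"], errors="ignore")
    rows = {}
    for col in numeric.columns:
        s = numeric[col].dropna()
        rows[col] = {
            "mean": s.mean(), "std": s.std(ddof=1), "min": s.min(),
            "25%": s.quantile(0.25), "50%": s.quantile(0.50),
            "75%": s.quantile(0.75), "max": s.max(),
        }
    return pd.DataFrame(rows).T[["mean", "std", "min", "25%", "50%", "75%", "max"]]
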