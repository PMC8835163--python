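"""Seeded synthetic indicator panels.

The worked analysis needs two kinds of input panels:

* an *economic* panel of five national macro indicators — GDP in current
  prices, a real-wage index (previous year = 100), a consumer-price
  inflation index (previous year = 100) with a 102.5 target, the registered
  unemployment rate, and the central budget deficit — emulating two decades
  of annual statistics for a converging European economy;
* a *survey-style* panel of five social-climate scores on a 0-100 scale
  (system assessment, sense of monetary availability, social capital,
  sense of threat, sense of wealth).

The generator reproduces the statistical *envelope* of such data — the
location, spread and min/max bounds of each series, plus a plausible
trend/persistence structure — not any particular country's trajectory.
Values that would leave the configured bounds are clipped and the clipping
is logged, never silent.  All randomness flows through one
``numpy.random.Generator`` built from an explicit seed, so identical
(seed, config) pairs give identical panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateInputError
from .preprocessing import IndicatorPanel, IndicatorSeries, Orientation

__all__ = [
    "SeriesSpec",
    "GeneratorConfig",
    "economic_config",
    "survey_config",
    "generate_panel",
    "generate_economic_panel",
    "generate_survey_panel",
]

logger = logging.getLogger(__name__)

_MODELS = ("geometric", "iid", "ar1", "walk")


@dataclass(frozen=True)
class SeriesSpec:
    """Stochastic model for one synthetic indicator series.

    ``model`` is one of:

    * ``geometric`` — exponential drift from ``low`` towards ``high`` over
      the window with multiplicative lognormal noise of log-sd ``sd``;
    * ``iid``  — independent draws from Normal(``mean``, ``sd``);
    * ``ar1``  — AR(1) around ``mean`` with persistence ``ar`` and
      innovation sd ``sd``;
    * ``walk`` — random walk started uniformly inside the central half of
      the bounds, step sd ``sd``.

    All models are clipped to ``[low, high]``.
    """

    name: str
    model: str
    low: float
    high: float
    sd: float
    mean: float | None = None
    ar: float = 0.5
    orientation: Orientation = Orientation.STIMULANT
    target: float | None = None

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise DegenerateInputError(f"unknown series model {self.model!r}")
        if not (np.isfinite(self.low) and np.isfinite(self.high) and self.low < self.high):
            raise DegenerateInputError(f"series {self.name!r}: bounds must be finite with low < high")
        if self.sd <= 0:
            raise DegenerateInputError(f"series {self.name!r}: sd must be positive")
        if self.model in ("iid", "ar1") and self.mean is None:
            raise DegenerateInputError(f"series {self.name!r}: model {self.model!r} needs a mean")
        if self.model == "ar1" and not abs(self.ar) < 1:
            raise DegenerateInputError(f"series {self.name!r}: AR(1) persistence must satisfy |ar| < 1")


@dataclass(frozen=True)
class GeneratorConfig:
    """A panel blueprint: period axis plus one :class:`SeriesSpec` each."""

    series: tuple[SeriesSpec, ...]
    n_periods: int = 20
    start_period: int = 2000

    def __post_init__(self) -> None:
        if self.n_periods < 3:
            raise DegenerateInputError("n_periods must be >= 3")
        if len(self.series) < 1:
            raise DegenerateInputError("config must declare at least one series")


def economic_config(n_periods: int = 20, start_period: int = 2000) -> GeneratorConfig:
    """Default economic panel blueprint (annual macro series, 20 periods)."""
    return GeneratorConfig(
        n_periods=n_periods,
        start_period=start_period,
        series=(
            SeriesSpec("gdp", "geometric", low=748_483, high=2_287_738, sd=0.03),
            SeriesSpec("remuneration", "iid", low=100.1, high=105.9, mean=103.0, sd=1.78,),
            SeriesSpec("inflation", "ar1", low=99.1, high=110.1, mean=102.5, sd=2.5,
                       ar=0.5, orientation=Orientation.NOMINANT, target=102.5),
            SeriesSpec("unemployment", "walk", low=5.2, high=20.0, sd=1.5,
                       orientation=Orientation.DESTIMULANT),
            SeriesSpec("budget_deficit", "iid", low=10_406, high=46_160, mean=29_637, sd=10_895,
                       orientation=Orientation.DESTIMULANT),
        ),
    )


def survey_config(n_periods: int = 20, start_period: int = 2000) -> GeneratorConfig:
    """Default survey-style social panel: 0-100 scores with AR(1) drift.

    Sense of threat is treated as a destimulant (more perceived threat is
    worse); the other four scores are stimulants.
    """
    def spec(name: str, mean: float, orientation: Orientation = Orientation.STIMULANT) -> SeriesSpec:
        # innovation sd chosen so the stationary spread spans the 5-95 scale
        return SeriesSpec(name, "ar1", low=5.0, high=95.0, mean=mean, sd=15.0, ar=0.6,
                          orientation=orientation)

    return GeneratorConfig(
        n_periods=n_periods,
        start_period=start_period,
        series=(
            spec("system_assessment", 55.0),
            spec("monetary_availability", 50.0),
            spec("social_capital", 60.0),
            spec("sense_of_threat", 40.0, Orientation.DESTIMULANT),
            spec("sense_of_wealth", 45.0),
        ),
    )


def _clip_logged(values: np.ndarray, spec: SeriesSpec) -> np.ndarray:
    clipped = np.clip(values, spec.low, spec.high)
    n_clipped = int(np.sum(clipped != values))
    if n_clipped:
        logger.info(
            "series %r: clipped %d of %d values into [%g, %g]",
            spec.name, n_clipped, values.size, spec.low, spec.high,
        )
    return clipped


def _simulate(spec: SeriesSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.model == "geometric":
        # drift calibrated so the noiseless path spans [low, high] over the window
        rate = (spec.high / spec.low) ** (1.0 / max(n - 1, 1))
        path = spec.low * rate ** np.arange(n)
        values = path * rng.lognormal(mean=0.0, sigma=spec.sd, size=n)
    elif spec.model == "iid":
        values = rng.normal(spec.mean, spec.sd, size=n)
    elif spec.model == "ar1":
        stationary_sd = spec.sd / np.sqrt(1.0 - spec.ar**2)
        level = rng.normal(spec.mean, stationary_sd)
        innovations = rng.normal(0.0, spec.sd, size=n - 1)
        values = np.empty(n)
        values[0] = level
        for t in range(1, n):
            level = spec.mean + spec.ar * (level - spec.mean) + innovations[t - 1]
            values[t] = level
    else:  # walk
        span = spec.high - spec.low
        start = rng.uniform(spec.low + 0.25 * span, spec.high - 0.25 * span)
        steps = rng.normal(0.0, spec.sd, size=n)
        steps[0] = 0.0
        values = start + np.cumsum(steps)
    return _clip_logged(values, spec)


def generate_panel(config: GeneratorConfig, seed: int) -> IndicatorPanel:
    """Draw one panel from a blueprint; identical (config, seed) pairs give
    identical panels."""
    rng = np.random.default_rng(seed)
    periods = tuple(range(config.start_period, config.start_period + config.n_periods))
    series = tuple(
        IndicatorSeries(
            name=spec.name,
            values=_simulate(spec, config.n_periods, rng),
            orientation=spec.orientation,
            target=spec.target,
        )
        for spec in config.series
    )
    return IndicatorPanel(periods=periods, series=series)


def generate_economic_panel(seed: int, n_periods: int = 20, start_period: int = 2000) -> IndicatorPanel:
    return generate_panel(economic_config(n_periods, start_period), seed)


def generate_survey_panel(seed: int, n_periods: int = 20, start_period: int = 2000) -> IndicatorPanel:
    return generate_panel(survey_config(n_periods, start_period), seed)
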