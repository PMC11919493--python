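"""How long until a gene's polymorphic space is exhausted.

Neutral-theory accounting equates the target number of distinct variants
(the space size ``k**L``, or an effective space size) with the number of
mutant gene copies produced:

* ``unlimited_doubling``: a population doubling every generation from
  ``N0`` replicants produces ``mu * N0 * 2**n`` variants after ``n``
  generations, so ``n = log2(k**L / (mu * N0))``.
* ``constant_Ne``: a constant effective population produces
  ``mu * Ne * n`` variants, so ``n = k**L / (mu * Ne)`` -- a number that
  can exceed native floating range and is carried in log10.

Defaults: ``mu = 2.54e-10`` substitutions per site per generation (a slow,
well-characterised bacterial rate) and a 20-minute generation time for
*E. coli*-style wall-clock conversions.  The 20-minute default is an
inference: it is the generation time under which 272 generations come to
roughly 4 days and 3.48e73 generations to 1.32e69 years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Union

from .space_math import SemantideSpec, space_log_size

MINUTES_PER_YEAR = 525_960.0  # Julian year
MINUTES_PER_DAY = 1_440.0

DEFAULT_MU = 2.54e-10


class Regime(str, Enum):
    UNLIMITED_DOUBLING = "unlimited_doubling"
    CONSTANT_NE = "constant_Ne"


class AlreadyExhaustedError(ValueError):
    """The space is already covered at n = 0 (mu * N >= k**L)."""


@dataclass(frozen=True)
class LogQuantity:
    """A non-negative quantity carried as its log10.

    Keeps counts like 3.48e73 generations exact where a float would still
    cope, and counts like 4**120 exact where it would not.
    """

    log10: float

    @classmethod
    def from_value(cls, value: float) -> "LogQuantity":
        if value < 0:
            raise ValueError("LogQuantity represents non-negative values")
        if value == 0:
            return cls(log10=-math.inf)
        return cls(log10=math.log10(value))

    @property
    def value(self) -> float:
        """Native float value; ``inf`` if the quantity exceeds float range."""
        if self.log10 == -math.inf:
            return 0.0
        try:
            return 10.0 ** self.log10
        except OverflowError:
            return math.inf

    def mantissa_exponent(self) -> tuple[float, int]:
        """(m, e) with value = m * 10**e and 1 <= m < 10."""
        if self.log10 == -math.inf:
            return 0.0, 0
        e = math.floor(self.log10)
        m = 10.0 ** (self.log10 - e)
        if m >= 10.0:  # guard rounding at the boundary
            m /= 10.0
            e += 1
        return m, e

    def sci(self, sig: int = 3) -> str:
        """Scientific-notation string to ``sig`` significant figures."""
        m, e = self.mantissa_exponent()
        m = round(m, sig - 1)
        if m >= 10.0:
            m /= 10.0
            e += 1
        if self.log10 == -math.inf:
            return "0"
        return f"{m:.{sig - 1}f}e{e:+03d}"

    def times(self, factor: float) -> "LogQuantity":
        if factor <= 0:
            raise ValueError("factor must be positive")
        return LogQuantity(self.log10 + math.log10(factor))

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class TimeScale:
    """Conversion from generations to wall-clock time."""

    generation_time_minutes: float = 20.0

    def __post_init__(self) -> None:
        if self.generation_time_minutes <= 0:
            raise ValueError("generation_time_minutes must be > 0")


@dataclass(frozen=True)
class ExhaustionScenario:
    """Inputs to the exhaustion calculation for one demographic regime.

    ``space_log10`` may come from a naive :class:`SemantideSpec` or from an
    effective (constrained) space; anything exposing a log10 size works via
    the ``space`` argument of :func:`generations_to_exhaust`.
    """

    space_log10: float
    mu: float = DEFAULT_MU
    n0: float = 1
    ne: float = 1.0
    regime: Regime = Regime.UNLIMITED_DOUBLING

    def __post_init__(self) -> None:
        if not 0 < self.mu <= 1:
            raise ValueError(f"mu must be in (0, 1], got {self.mu}")
        if self.n0 < 1:
            raise ValueError("N0 must be >= 1")
        if self.ne < 1:
            raise ValueError("Ne must be >= 1")

    @classmethod
    def from_space(
        cls,
        space: Union[SemantideSpec, float],
        **kwargs,
    ) -> "ExhaustionScenario":
        if isinstance(space, SemantideSpec):
            log10_size = space_log_size(space)
        else:
            log10_size = float(space)
        return cls(space_log10=log10_size, **kwargs)


def generations_to_exhaust(scenario: ExhaustionScenario) -> LogQuantity:
    """Generations ``n`` needed to produce every variant in the space.

    Returns a :class:`LogQuantity`; under ``unlimited_doubling`` the value
    is desk-scale (hundreds), under ``constant_Ne`` it can reach 1e73.

    Raises :class:`AlreadyExhaustedError` when the first generation already
    covers the space.
    """
    log10_mu = math.log10(scenario.mu)
    if scenario.regime is Regime.UNLIMITED_DOUBLING:
        log10_initial = log10_mu + math.log10(scenario.n0)
        if log10_initial >= scenario.space_log10:
            raise AlreadyExhaustedError(
                "mu * N0 already covers the space at n = 0"
            )
        n = (scenario.space_log10 - log10_initial) / math.log10(2.0)
        return LogQuantity.from_value(n)
    # constant Ne: n = k**L / (mu * Ne)
    log10_n = scenario.space_log10 - (log10_mu + math.log10(scenario.ne))
    if log10_n <= 0:
        raise AlreadyExhaustedError(
            "mu * Ne covers the space within a single generation"
        )
    return LogQuantity(log10_n)


@dataclass(frozen=True)
class Duration:
    """A duration carried in log10 minutes, convertible to days/years."""

    minutes: LogQuantity

    @property
    def days(self) -> LogQuantity:
        if self.minutes.log10 == -math.inf:
            return self.minutes
        return LogQuantity(self.minutes.log10 - math.log10(MINUTES_PER_DAY))

    @property
    def years(self) -> LogQuantity:
        if self.minutes.log10 == -math.inf:
            return self.minutes
        return LogQuantity(self.minutes.log10 - math.log10(MINUTES_PER_YEAR))


def generations_to_duration(
    n: Union[LogQuantity, float], ts: TimeScale
) -> Duration:
    """Wall-clock duration of ``n`` generations under ``ts``.

    Accepts a plain float or a log-represented count; exact in log space
    for huge ``n``.
    """
    if not isinstance(n, LogQuantity):
        if n < 0:
            raise ValueError("generation count must be >= 0")
        n = LogQuantity.from_value(float(n))
    return Duration(minutes=n.times(ts.generation_time_minutes))
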