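"""Stage-specific vital rates and the canonical censoring scenarios.

A :class:`VitalRates` set holds the annual survival probability of each
post-fledging life stage of a long-lived territorial raptor — juvenile
(first year after fledging), subadult (three further years, a single
shared rate), floater (non-breeding adult), breeder — together with the
female-fledgling reproductive rate ``f`` (female fledglings per female
territory holder per year) and one standard error per rate.

Three named scenarios correspond to three treatments of cause-specific
mortality in the survival analysis: all observed deaths included, wind
turbine blade-strike deaths censored, and all known human-caused deaths
censored.  The shipped values are the published rounded estimates; they
are the canonical inputs of every downstream model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

__all__ = ["VitalRates", "CANONICAL_SCENARIOS", "canonical_rates"]


@dataclass(frozen=True)
class VitalRates:
    """Annual stage survival probabilities and female fecundity.

    Parameters
    ----------
    s_juv, s_sub, s_float, s_breed:
        Annual survival probability of juveniles, subadults (shared by
        all three subadult years), floaters, and breeders.
    f:
        Female fledglings per female territory holder per year.
    se_* :
        One non-negative standard error per rate (0 = treated as known).
    scenario:
        Free-text label, e.g. ``"turbine_censored"``.
    """

    s_juv: float
    s_sub: float
    s_float: float
    s_breed: float
    f: float
    se_juv: float = 0.0
    se_sub: float = 0.0
    se_float: float = 0.0
    se_breed: float = 0.0
    se_f: float = 0.0
    scenario: str = ""

    def __post_init__(self) -> None:
        for name in ("s_juv", "s_sub", "s_float", "s_breed"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p!r} is not a probability")
        if self.f < 0:
            raise ValueError(f"f={self.f!r} must be non-negative")
        for name in ("se_juv", "se_sub", "se_float", "se_breed", "se_f"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def with_(self, **kwargs) -> "VitalRates":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def survivals(self) -> dict[str, float]:
        return {
            "juvenile": self.s_juv,
            "subadult": self.s_sub,
            "floater": self.s_float,
            "breeder": self.s_breed,
        }


# Published rounded annual survival estimates (SE) per censoring scenario,
# and f = 0.2313 (SE 0.040) female fledglings per female territory holder.
CANONICAL_SCENARIOS: dict[str, VitalRates] = {
    "all_deaths": VitalRates(
        s_juv=0.842, s_sub=0.801, s_float=0.839, s_breed=0.905, f=0.2313,
        se_juv=0.038, se_sub=0.028, se_float=0.040, se_breed=0.026, se_f=0.040,
        scenario="all_deaths",
    ),
    "turbine_censored": VitalRates(
        s_juv=0.842, s_sub=0.921, s_float=0.870, s_breed=0.920, f=0.2313,
        se_juv=0.038, se_sub=0.020, se_float=0.037, se_breed=0.024, se_f=0.040,
        scenario="turbine_censored",
    ),
    "human_censored": VitalRates(
        s_juv=0.893, s_sub=0.978, s_float=0.924, s_breed=0.935, f=0.2313,
        se_juv=0.032, se_sub=0.011, se_float=0.030, se_breed=0.022, se_f=0.040,
        scenario="human_censored",
    ),
}


def canonical_rates(scenario: str) -> VitalRates:
    """Look up a canonical scenario by name.

    Raises ``KeyError`` with the list of known names on a miss.
    """
    try:
        return CANONICAL_SCENARIOS[scenario]
    except KeyError:
        raise KeyError(
            f"unknown scenario {scenario!r}; "
            f"known: {sorted(CANONICAL_SCENARIOS)}"
        ) from None


def iter_scenarios() -> Iterator[VitalRates]:
    yield from CANONICAL_SCENARIOS.values()
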