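"""Known-fate survival estimation from staggered-entry capture histories.

The data model follows the classical radio-telemetry design: each tagged
individual contributes a binomial trial to every seasonal interval in
which it was relocated, deaths are recorded in the interval of death, and
individuals are removed from the risk set from the interval in which they
are censored (transmitter failure, signal loss, emigration).  The
likelihood is product-binomial over intervals,

    L = prod_i  S_i^(n_i - d_i) * (1 - S_i)^(d_i),

with n_i at risk and d_i deaths in interval i.  Four candidate
parameterisations are supported — survival constant over seasons S(.),
time-varying S(t), sex-dependent S(sex), and the interaction S(sex x t) —
ranked by small-sample AICc.  Because every parameterisation pools
disjoint binomial cells, the maximum-likelihood estimates have exact
closed forms (pooled (n-d)/n per cell); a logit-scale numerical
optimisation is retained as an internal cross-check.

Annual survival is the product of four seasonal survivals, with variance
by the delta method and confidence limits computed on the logit scale and
back-transformed so they stay inside [0, 1].

Analytic "what-if" censoring (removing deaths of a named cause set from
the mortality record) is provided by :func:`censor_by_cause`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .telemetry_io import (
    CaptureHistory,
    FATALITY_CAUSES,
    SeasonInterval,
)

__all__ = [
    "RiskSet",
    "SurvivalFit",
    "AnnualSurvival",
    "MODEL_STRUCTURES",
    "build_risk_sets",
    "censor_by_cause",
    "fit_known_fate",
    "rank_models",
    "annual_from_seasonal",
]

MODEL_STRUCTURES = ("constant", "time", "sex", "sex_by_time")

#: minimum per-interval sample size retained, as used in the source study
DEFAULT_MIN_N = 11


class EmptyRiskSetError(ValueError):
    """No interval reached the minimum sample size."""


@dataclass
class RiskSet:
    """Per-interval (optionally per-sex) counts of exposure and deaths.

    ``table`` has columns ``interval`` (SeasonInterval), ``sex`` (a label,
    ``"all"`` when not sex-split), ``n_risk`` and ``n_deaths``.
    """

    table: pd.DataFrame
    by_sex: bool = False

    def __post_init__(self) -> None:
        t = self.table
        if (t["n_deaths"] > t["n_risk"]).any():
            raise ValueError("n_deaths exceeds n_risk in a risk set")
        if (t["n_risk"] < 0).any():
            raise ValueError("negative exposure in a risk set")

    @classmethod
    def from_counts(
        cls,
        n_risk: Sequence[int],
        n_deaths: Sequence[int],
        intervals: Optional[Sequence] = None,
        sex: str = "all",
    ) -> "RiskSet":
        """Build a single-sex risk set directly from count arrays."""
        if intervals is None:
            intervals = list(range(len(n_risk)))
        return cls(
            pd.DataFrame(
                {
                    "interval": list(intervals),
                    "sex": sex,
                    "n_risk": list(n_risk),
                    "n_deaths": list(n_deaths),
                }
            )
        )

    @property
    def intervals(self) -> list:
        seen: dict = {}
        for iv in self.table["interval"]:
            seen.setdefault(iv, None)
        return list(seen)

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    @property
    def n_eff(self) -> int:
        """Effective sample size: total individual-intervals of exposure."""
        return int(self.table["n_risk"].sum())

    @property
    def total_deaths(self) -> int:
        return int(self.table["n_deaths"].sum())

    def pooled_over_sex(self) -> "RiskSet":
        g = (
            self.table.groupby("interval", sort=False)[["n_risk", "n_deaths"]]
            .sum()
            .reset_index()
        )
        g["sex"] = "all"
        return RiskSet(g[["interval", "sex", "n_risk", "n_deaths"]])


def build_risk_sets(
    histories: Iterable[CaptureHistory],
    stage: Optional[str] = None,
    min_n: int = DEFAULT_MIN_N,
    by_sex: bool = False,
) -> RiskSet:
    """Tally at-risk and death counts per seasonal interval.

    An individual contributes to an interval only when relocated in it:
    ``alive-detected`` and ``dead`` states count as exposure (the latter
    also as a death); ``not-detected`` intervals contribute nothing; a
    ``censored`` state removes the individual from its interval onward.

    Trailing intervals whose pooled sample size falls below ``min_n``
    (default 11, the study's threshold) are truncated; interior intervals
    are kept regardless so the retained series stays contiguous.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    counts: dict[tuple, np.ndarray] = {}
    for h in histories:
        if stage is not None:
            # "subadult" groups the three subadult years
            match = h.stage_at_entry == stage or (
                stage == "subadult"
                and h.stage_at_entry.startswith("subadult")
            )
            if not match:
                continue
        if by_sex and h.sex == "unknown":
            continue  # unknown sex cannot enter sex-structured fits
        sex = h.sex if by_sex else "all"
        for iv, state in h.records:
            if state == "alive-detected":
                key = (iv, sex)
                counts.setdefault(key, np.zeros(2, dtype=int))[0] += 1
            elif state == "dead":
                key = (iv, sex)
                c = counts.setdefault(key, np.zeros(2, dtype=int))
                c[0] += 1
                c[1] += 1
            # not-detected / censored: no exposure in this interval
    if not counts:
        raise EmptyRiskSetError("no exposure in any interval")
    rows = [
        {"interval": iv, "sex": sex, "n_risk": int(c[0]),
         "n_deaths": int(c[1])}
        for (iv, sex), c in counts.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        by=["interval", "sex"],
        key=lambda s: s.map(lambda x: getattr(x, "_key", x)),
        kind="stable",
    ).reset_index(drop=True)

    pooled = df.groupby("interval", sort=False)["n_risk"].sum()
    order = sorted(pooled.index, key=lambda iv: getattr(iv, "_key", iv))
    keep_through = -1
    for i, iv in enumerate(order):
        if pooled[iv] >= min_n:
            keep_through = i
    if keep_through < 0:
        raise EmptyRiskSetError(
            f"no interval reaches the minimum sample size {min_n}"
        )
    retained = set(order[: keep_through + 1])
    df = df[df["interval"].isin(retained)].reset_index(drop=True)
    return RiskSet(df, by_sex=by_sex)


def censor_by_cause(
    histories: Iterable[CaptureHistory],
    causes_to_censor: Iterable[str],
) -> list[CaptureHistory]:
    """Re-censor deaths of the named causes at their death interval.

    Returns new histories; deaths whose cause is in the set become
    ``censored`` in the same interval (the individual leaves the risk set
    there instead of dying).  Undiagnosed fatalities are never censored —
    they are treated as natural deaths to keep the anthropogenic-mortality
    estimate a minimum — so "Undiagnosed fatality" is ignored if passed.
    """
    causes = set(causes_to_censor)
    for c in causes:
        if c not in FATALITY_CAUSES:
            raise ValueError(f"unknown fatality cause {c!r}")
    causes.discard("Undiagnosed fatality")
    out = []
    for h in histories:
        if h.terminal_state == "dead" and h.cause in causes:
            h2 = h.copy()
            iv, _ = h2.records[-1]
            h2.records[-1] = (iv, "censored")
            h2.cause = None
            h2.validate()
            out.append(h2)
        else:
            out.append(h.copy())
    return out


# --------------------------------------------------------------------------
# Model fitting

@dataclass
class SurvivalFit:
    """A fitted known-fate model.

    ``estimates`` are seasonal survival probabilities, one per parameter
    cell (ordering given by ``param_names``); ``vcov`` is their variance
    matrix (diagonal: cells are disjoint binomials); ``cells`` maps each
    risk-set row to its parameter index.
    """

    model: str
    param_names: list[str]
    estimates: np.ndarray
    vcov: np.ndarray
    logL: float
    K: int
    n_eff: int
    aicc: float
    boundary: bool = False
    risk_set: Optional[RiskSet] = None

    def __post_init__(self) -> None:
        if np.any(self.estimates < 0) or np.any(self.estimates > 1):
            raise ValueError("survival estimates outside [0, 1]")


def _aicc(logL: float, K: int, n_eff: int) -> float:
    if n_eff - K - 1 <= 0:
        return np.inf
    return -2.0 * logL + 2 * K + 2 * K * (K + 1) / (n_eff - K - 1)


def _cells_for(risk: RiskSet, model: str) -> tuple[list[str], np.ndarray]:
    """Parameter-cell labels and the row -> cell assignment."""
    t = risk.table
    if model == "constant":
        return ["S"], np.zeros(len(t), dtype=int)
    if model == "time":
        ivs = risk.intervals
        idx = {iv: i for i, iv in enumerate(ivs)}
        return (
            [f"S[{iv}]" for iv in ivs],
            t["interval"].map(idx).to_numpy(),
        )
    if model in ("sex", "sex_by_time"):
        if not risk.by_sex:
            raise ValueError(f"model {model!r} needs a sex-split risk set")
        sexes = sorted(t["sex"].unique())
        if model == "sex":
            idx = {s: i for i, s in enumerate(sexes)}
            return (
                [f"S[{s}]" for s in sexes],
                t["sex"].map(idx).to_numpy(),
            )
        ivs = risk.intervals
        labels, idx = [], {}
        for s in sexes:
            for iv in ivs:
                idx[(s, iv)] = len(labels)
                labels.append(f"S[{s},{iv}]")
        assign = np.array(
            [idx[(row.sex, row.interval)] for row in t.itertuples()]
        )
        return labels, assign
    raise ValueError(
        f"unknown model {model!r}; choose from {MODEL_STRUCTURES}"
    )


def fit_known_fate(risk_set: RiskSet, model: str = "constant") -> SurvivalFit:
    """Maximum-likelihood fit of one candidate model.

    Each parameter cell pools disjoint binomial counts, so the MLE is the
    exact pooled proportion surviving, S = (sum n - sum d) / sum n, with
    variance S(1-S)/sum n from the inverse observed information.  Cells at
    the boundary (no deaths, or all deaths) get a zero variance and set
    the ``boundary`` flag.
    """
    if len(risk_set.table) == 0:
        raise EmptyRiskSetError("empty risk set")
    names, assign = _cells_for(risk_set, model)
    K = len(names)
    n = risk_set.table["n_risk"].to_numpy(dtype=float)
    d = risk_set.table["n_deaths"].to_numpy(dtype=float)
    N = np.bincount(assign, weights=n, minlength=K)
    D = np.bincount(assign, weights=d, minlength=K)
    if np.any(N == 0):
        raise EmptyRiskSetError("a parameter cell has no exposure")
    S = (N - D) / N
    var = S * (1.0 - S) / N  # zero at boundaries
    with np.errstate(divide="ignore", invalid="ignore"):
        logL = float(
            np.sum(np.where(N - D > 0, (N - D) * np.log(S), 0.0))
            + np.sum(np.where(D > 0, D * np.log(1.0 - S), 0.0))
        )
    n_eff = int(N.sum())
    return SurvivalFit(
        model=model,
        param_names=names,
        estimates=S,
        vcov=np.diag(var),
        logL=logL,
        K=K,
        n_eff=n_eff,
        aicc=_aicc(logL, K, n_eff),
        boundary=bool(np.any(S == 0.0) or np.any(S == 1.0)),
        risk_set=risk_set,
    )


def _fit_logit_optim(risk_set: RiskSet, model: str) -> np.ndarray:
    """Logit-scale numerical MLE; cross-check for the closed form.

    Starts at the closed-form estimates (nudged off the boundary) and
    maximises the product-binomial log-likelihood with its analytic
    gradient.  Exposed for testing, not used in the primary path.
    """
    names, assign = _cells_for(risk_set, model)
    K = len(names)
    n = risk_set.table["n_risk"].to_numpy(dtype=float)
    d = risk_set.table["n_deaths"].to_numpy(dtype=float)
    N = np.bincount(assign, weights=n, minlength=K)
    D = np.bincount(assign, weights=d, minlength=K)
    S0 = np.clip((N - D) / N, 1e-6, 1 - 1e-6)

    def negll_grad(beta: np.ndarray) -> tuple[float, np.ndarray]:
        S = special.expit(beta)
        ll = np.sum((N - D) * np.log(S) + D * np.log(1.0 - S))
        # d ll / d beta = (N - D)(1 - S) - D S
        grad = (N - D) * (1.0 - S) - D * S
        return -ll, -grad

    res = optimize.minimize(
        negll_grad, special.logit(S0), jac=True, method="BFGS",
        options={"gtol": 1e-10},
    )
    if not res.success and np.linalg.norm(res.jac) > 1e-5:
        raise RuntimeError(f"logit-scale optimisation failed: {res.message}")
    return special.expit(res.x)


# --------------------------------------------------------------------------
# Model ranking

def rank_models(fits: Sequence[SurvivalFit]) -> pd.DataFrame:
    """AICc ranking with Akaike weights and evidence ratios.

    All fits must share the same effective sample size (same data).  Ties
    in AICc are broken in favour of fewer parameters.
    """
    if not fits:
        raise ValueError("no fits to rank")
    n_effs = {f.n_eff for f in fits}
    if len(n_effs) != 1:
        raise ValueError(
            f"fits are not on identical data (n_eff values {sorted(n_effs)})"
        )
    df = pd.DataFrame(
        {
            "model": [f.model for f in fits],
            "K": [f.K for f in fits],
            "logL": [f.logL for f in fits],
            "AICc": [f.aicc for f in fits],
        }
    )
    df["dAICc"] = df["AICc"] - df["AICc"].min()
    w = np.exp(-df["dAICc"] / 2.0)
    df["weight"] = w / w.sum()
    df = df.sort_values(["AICc", "K"], kind="stable").reset_index(drop=True)
    df["evidence_ratio"] = df["weight"].iloc[0] / df["weight"]
    return df


# --------------------------------------------------------------------------
# Annual survival

@dataclass(frozen=True)
class AnnualSurvival:
    S_hat: float
    SE: float
    ci95: tuple[float, float]
    scenario: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (0.0 <= lo <= self.S_hat <= hi <= 1.0):
            raise ValueError("annual-survival CI ordering violated")


def _logit_ci(S: float, se: float, z: float = 1.959963984540054) -> tuple[float, float]:
    if se == 0.0 or S <= 0.0 or S >= 1.0:
        return (S, S)
    se_logit = se / (S * (1.0 - S))
    lo = special.expit(special.logit(S) - z * se_logit)
    hi = special.expit(special.logit(S) + z * se_logit)
    return (float(lo), float(hi))


def annual_from_seasonal(
    fit: SurvivalFit,
    seasons_per_year: int = 4,
    scenario: str = "",
) -> AnnualSurvival:
    """Annual survival as the product of seasonal survivals.

    For the constant model S_annual = S^seasons_per_year with the
    closed-form delta variance (k S^(k-1))^2 var(S); for the time model
    the product runs over the first ``seasons_per_year`` retained
    intervals with gradient prod/S_i and the fit's full variance matrix.
    Confidence limits are computed on the logit scale.
    """
    if fit.model == "constant":
        S = float(fit.estimates[0])
        v = float(fit.vcov[0, 0])
        k = seasons_per_year
        S_ann = S**k
        var = (k * S ** (k - 1)) ** 2 * v
    elif fit.model == "time":
        if fit.K < seasons_per_year:
            raise ValueError(
                f"need >= {seasons_per_year} seasonal estimates, "
                f"fit has {fit.K}"
            )
        S_vec = fit.estimates[:seasons_per_year]
        V = fit.vcov[:seasons_per_year, :seasons_per_year]
        S_ann = float(np.prod(S_vec))
        if np.all(S_vec > 0):
            g = S_ann / S_vec
        else:  # gradient of the product at a zero estimate
            g = np.array(
                [np.prod(np.delete(S_vec, i)) for i in range(len(S_vec))]
            )
        var = float(g @ V @ g)
    else:
        raise ValueError(
            "annual survival is defined for the 'constant' and 'time' "
            f"structures, not {fit.model!r}; fit per sex instead"
        )
    se = float(np.sqrt(max(var, 0.0)))
    return AnnualSurvival(
        S_hat=float(S_ann), SE=se, ci95=_logit_ci(float(S_ann), se),
        scenario=scenario,
    )
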