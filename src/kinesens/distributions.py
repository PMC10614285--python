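"""Population distributions of the seven varied occupant characteristics.

The seven quantities varied in the braking sensitivity study are two
spinal-alignment principal-component scores, the neural delay of the
feedback controller, muscle physical cross-sectional area (PCSA),
adipose and passive-muscle tissue stiffness, and skin stiffness.  Their
dispersions come from literature-style inputs:

* coefficients of variation (CoV = SD / mean) pooled across studies by a
  two-stage unweighted average (within study over conditions, then over
  studies), then scaled by the nominal value to give an SD;
* normal / lognormal fits from a reported median and quartiles;
* uniform ranges where only between-study spread is available.

The skin stiffness has two material directions (along / across tension
lines) varied together: a single standard-normal score drives both
marginals comonotonically; the lognormal (across) marginal is the one
integrated in the sensitivity quadrature.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ParameterSpec",
    "StudyCoV",
    "pooled_cov",
    "cov_to_sd",
    "normal_from_quartiles",
    "lognormal_from_quartiles",
    "build_parameter_set",
    "default_parameter_config",
    "skin_coupled_along",
]

_Z75 = stats.norm.ppf(0.75)  # 0.6744897501960817

_FAMILIES = ("normal", "uniform", "lognormal")


@dataclass(frozen=True)
class ParameterSpec:
    """One varied quantity: distribution family, parameters and nominal.

    ``params`` is (mean, sd) for normal, (low, high) for uniform,
    (log_mean, log_sd) for lognormal.  ``nominal`` is the cut-point
    coordinate for this parameter and must lie inside the support.
    ``coupling`` labels a group of jointly varied parameters.
    """

    name: str
    family: str
    params: tuple[float, float]
    units: str = ""
    nominal: float | None = None
    coupling: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"{self.name}: unknown family {self.family!r}")
        a, b = self.params
        if self.family == "normal" and b <= 0:
            raise ValueError(f"{self.name}: sd must be positive")
        if self.family == "uniform" and b <= a:
            raise ValueError(f"{self.name}: need high > low")
        if self.family == "lognormal" and b <= 0:
            raise ValueError(f"{self.name}: log_sd must be positive")
        if self.nominal is None:
            object.__setattr__(self, "nominal", self.center())
        if not self._in_support(self.nominal):
            raise ValueError(f"{self.name}: nominal {self.nominal} outside support")

    def center(self) -> float:
        """Distribution centre: mean (normal/uniform) or median (lognormal)."""
        a, b = self.params
        if self.family == "normal":
            return a
        if self.family == "uniform":
            return 0.5 * (a + b)
        return math.exp(a)

    def _in_support(self, x: float) -> bool:
        if self.family == "uniform":
            return self.params[0] <= x <= self.params[1]
        if self.family == "lognormal":
            return x > 0
        return math.isfinite(x)

    def frozen(self):
        """The scipy frozen distribution for this spec."""
        a, b = self.params
        if self.family == "normal":
            return stats.norm(loc=a, scale=b)
        if self.family == "uniform":
            return stats.uniform(loc=a, scale=b - a)
        return stats.lognorm(s=b, scale=math.exp(a))


@dataclass(frozen=True)
class StudyCoV:
    """Per-condition coefficients of variation reported by one study."""

    study_id: str
    condition_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.condition_values:
            raise ValueError(f"{self.study_id}: no condition values")
        if any(v <= 0 for v in self.condition_values):
            raise ValueError(f"{self.study_id}: CoV values must be positive")

    @property
    def average(self) -> float:
        return float(np.mean(self.condition_values))


def pooled_cov(studies: list[StudyCoV]) -> float:
    """Two-stage unweighted pooling of coefficients of variation.

    First average within each study over its reported conditions, then
    average those per-study means with equal weight.
    """
    if not studies:
        raise ValueError("no studies supplied")
    return float(np.mean([s.average for s in studies]))


def cov_to_sd(cov: float, nominal: float) -> float:
    """Standard deviation in nominal units: sd = CoV * nominal."""
    if cov <= 0 or nominal <= 0:
        raise ValueError("cov and nominal must be positive")
    return cov * nominal


def normal_from_quartiles(median: float, q25: float, q75: float) -> tuple[float, float]:
    """Fit a normal distribution to a median and quartile pair.

    For symmetric inputs the fit is exact: mean = median,
    sd = (q75 - q25) / (2 z_0.75).  Asymmetric triples are fitted by
    least squares over the three quantile equations
    (median = mean, q25 = mean - z sd, q75 = mean + z sd).
    """
    if not (q25 < median < q75):
        raise ValueError("require q25 < median < q75")
    # Least squares for (mean, sd) over the three quantile equations has a
    # closed form: mean from the z=0 and +-z rows, sd from the spread.
    # Stationarity of sum of squared residuals gives:
    #   mean = (median + q25 + q75 + z*sd - z*sd) ... solve the 2x2 system.
    z = _Z75
    # Design matrix rows: [1, 0], [1, -z], [1, z]; targets median, q25, q75.
    A = np.array([[1.0, 0.0], [1.0, -z], [1.0, z]])
    y = np.array([median, q25, q75])
    (mean, sd), *_ = np.linalg.lstsq(A, y, rcond=None)
    if sd <= 0:
        raise ValueError("fitted sd non-positive")
    return float(mean), float(sd)


def lognormal_from_quartiles(
    median: float, q25: float, q75: float
) -> tuple[float, float]:
    """Fit a lognormal by moment-matching quartiles in log space.

    log_mean = ln(median); log_sd = (ln q75 - ln q25) / (2 z_0.75).
    """
    if not (0 < q25 < median < q75):
        raise ValueError("require 0 < q25 < median < q75")
    log_mean = math.log(median)
    log_sd = (math.log(q75) - math.log(q25)) / (2.0 * _Z75)
    return float(log_mean), float(log_sd)


def skin_coupled_along(
    skin_spec: ParameterSpec, across_value: float | np.ndarray
):
    """Along-lines skin stiffness comonotone with the across value.

    The across (lognormal) value is mapped through its own CDF to a
    probability level, then through the along (normal) quantile
    function, so the two directions vary together.
    """
    along_mean = skin_spec.extra.get("along_mean", 0.1)
    along_sd = skin_spec.extra.get("along_sd", 0.028)
    u = skin_spec.frozen().cdf(across_value)
    return stats.norm(loc=along_mean, scale=along_sd).ppf(u)


# ---------------------------------------------------------------------------
# Default configuration (the study conditions)

_NEURAL_DELAY_STUDY_COVS = [
    StudyCoV("weight-drop EMG onset", (0.22,)),
    StudyCoV("drop direction/stature/age pooled", (0.15,)),
    StudyCoV("neck muscles x awareness pooled", (0.10,)),
]

_PCSA_STUDY_COVS = [
    StudyCoV("left-right CSA", (0.14,)),
    StudyCoV("baseline multi-site CSA", (0.21,)),
    StudyCoV("control-group CSA", (0.24,)),
    StudyCoV("no-lumbar-pain CSA", (0.16,)),
]


def default_parameter_config() -> dict:
    """Default 7-parameter configuration of the sensitivity study.

    Neural delay: nominal neck delay 20 ms (lumbar follows at 25/20 of
    the neck value), SD 3.16 ms (unrounded pooled CoV times nominal).
    Muscle PCSA: scale factor, SD equal to the pooled CoV 0.19.
    Tissue stiffness factors: uniform scale ranges (bounds are data).
    Skin: lognormal across-lines marginal (mu=-1.45, sigma=0.45 in log
    space) used for the quadrature, normal along-lines marginal
    (0.1, 0.028) coupled comonotonically.
    """
    return {
        "spine_pc1": {
            "family": "normal",
            "params": [0.0, 1.0],
            "units": "score SD",
            "nominal": 0.0,
        },
        "spine_pc2": {
            "family": "normal",
            "params": [0.0, 1.0],
            "units": "score SD",
            "nominal": 0.0,
        },
        "neural_delay": {
            "family": "normal",
            "params": [20.0, 3.16],
            "units": "ms",
            "nominal": 20.0,
        },
        "muscle_pcsa": {
            "family": "normal",
            "params": [1.0, 0.19],
            "units": "scale factor",
            "nominal": 1.0,
        },
        "adipose_props": {
            "family": "uniform",
            "params": [0.5, 1.5],
            "units": "stiffness scale",
            "nominal": 1.0,
        },
        "muscle_props": {
            "family": "uniform",
            "params": [0.5, 1.5],
            "units": "stiffness scale",
            "nominal": 1.0,
        },
        "skin_mu": {
            "family": "lognormal",
            "params": [-1.45, 0.45],
            "units": "strain parameter (across lines)",
            "coupling": "skin",
            "extra": {"along_mean": 0.1, "along_sd": 0.028},
        },
    }


PARAMETER_ORDER = (
    "spine_pc1",
    "spine_pc2",
    "neural_delay",
    "muscle_pcsa",
    "adipose_props",
    "muscle_props",
    "skin_mu",
)


def build_parameter_set(config: dict | None = None) -> list[ParameterSpec]:
    """Build the 7 ParameterSpecs from a configuration mapping.

    The configuration must contain exactly the seven canonical entries;
    each maps to family, params, units, optional nominal and coupling.
    """
    if config is None:
        config = default_parameter_config()
    missing = set(PARAMETER_ORDER) - set(config)
    extra = set(config) - set(PARAMETER_ORDER)
    if missing:
        raise ValueError(f"parameter config missing entries: {sorted(missing)}")
    if extra:
        raise ValueError(f"parameter config has unknown entries: {sorted(extra)}")
    specs = []
    for name in PARAMETER_ORDER:
        entry = config[name]
        specs.append(
            ParameterSpec(
                name=name,
                family=entry["family"],
                params=tuple(float(v) for v in entry["params"]),
                units=entry.get("units", ""),
                nominal=entry.get("nominal"),
                coupling=entry.get("coupling"),
                extra=dict(entry.get("extra", {})),
            )
        )
    return specs


def load_parameter_config(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def save_parameter_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(config, fh, indent=1)


def neural_delay_pooled_cov() -> float:
    """Pooled neural-delay CoV from the printed per-study averages."""
    return pooled_cov(_NEURAL_DELAY_STUDY_COVS)


def pcsa_pooled_cov() -> float:
    """Pooled muscle-CSA CoV from the printed per-study averages."""
    return pooled_cov(_PCSA_STUDY_COVS)
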