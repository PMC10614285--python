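"""Multiplicative dimensional reduction method (M-DRM) for global
sensitivity analysis from a one-at-a-time design.

The method approximates a multivariate response h(x) around a cut-point
c as a normalized product of univariate cuts,

    h(x) ~= h(c)^(1-n) * prod_i h(x_i, c_-i),

so the mean and mean square of each univariate cut,

    rho_i = sum_j w_ij h(x_ij, c_-i),
    theta_i = sum_j w_ij h(x_ij, c_-i)^2,

computed by Gauss quadrature against each parameter's distribution,
yield first-order (primary) sensitivity indices

    S_i = (theta_i / rho_i^2 - 1) / sum_k (theta_k / rho_k^2 - 1).

With n parameters and N Gauss points per parameter, sharing the nominal
run across all parameters requires n(N-1)+1 model evaluations.  For a
multiplicative response the indices coincide with Sobol first-order
indices; for general responses they are an approximation whose quality
degrades with interaction strength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import hermite_e, legendre
from scipy.interpolate import PchipInterpolator

from .distributions import ParameterSpec

__all__ = [
    "QuadratureRule",
    "DesignMatrix",
    "SensitivityResult",
    "quadrature_rule",
    "build_design",
    "mdrm_moments",
    "sensitivity_indices",
    "mdrm_approximate",
    "MDRMSensitivity",
    "MDRMResults",
    "DesignError",
]


class DesignError(ValueError):
    """Raised when a shared-nominal design cannot be constructed."""


@dataclass(frozen=True)
class QuadratureRule:
    """Gauss nodes and probability weights for one parameter."""

    parameter: str
    nodes: np.ndarray  # ascending, parameter units
    weights: np.ndarray  # positive, sum to 1

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)
        if np.any(np.diff(nodes) <= 0):
            raise ValueError(f"{self.parameter}: nodes must be strictly ascending")
        if np.any(weights <= 0):
            raise ValueError(f"{self.parameter}: weights must be positive")
        if abs(weights.sum() - 1.0) > 1e-12:
            raise ValueError(f"{self.parameter}: weights must sum to 1")

    @property
    def n_points(self) -> int:
        return len(self.nodes)

    @property
    def center_index(self) -> int:
        return (self.n_points - 1) // 2


def quadrature_rule(spec: ParameterSpec, n_points: int = 5) -> QuadratureRule:
    """Gauss quadrature against the parameter's distribution.

    normal    -> probabilists' Gauss-Hermite, scaled by sd, shifted by mean
    uniform   -> Gauss-Legendre mapped to [low, high], weights sum to 1
    lognormal -> Gauss-Hermite in log space, nodes exponentiated

    The rule integrates polynomials of degree <= 2N-1 exactly in the
    transformed (Gaussian or uniform) variable.
    """
    if n_points < 2:
        raise ValueError("need at least 2 Gauss points")
    a, b = spec.params
    if spec.family == "normal":
        z, w = hermite_e.hermegauss(n_points)
        nodes = a + b * z
        weights = w / w.sum()
    elif spec.family == "uniform":
        z, w = legendre.leggauss(n_points)
        nodes = a + (b - a) * (z + 1.0) / 2.0
        weights = w / w.sum()
    elif spec.family == "lognormal":
        z, w = hermite_e.hermegauss(n_points)
        nodes = np.exp(a + b * z)
        weights = w / w.sum()
    else:  # pragma: no cover - guarded by ParameterSpec
        raise ValueError(f"unknown family {spec.family!r}")
    return QuadratureRule(parameter=spec.name, nodes=nodes, weights=weights)


@dataclass(frozen=True)
class DesignMatrix:
    """One-at-a-time evaluation plan with a shared nominal run.

    ``runs`` is a DataFrame with run_id, label, and one physical-units
    column per parameter.  Labels are 'nominal' or '<param>:P<j>' with
    P1..PN indexing the ascending Gauss points (the centre point of an
    odd rule is the nominal itself and produces no extra run).
    """

    runs: pd.DataFrame
    parameters: tuple[str, ...]
    n_points: int

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def to_csv(self, path) -> None:
        self.runs.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_points: int) -> "DesignMatrix":
        runs = pd.read_csv(path)
        params = tuple(c for c in runs.columns if c not in ("run_id", "label"))
        return cls(runs=runs, parameters=params, n_points=n_points)


def build_design(
    params: list[ParameterSpec],
    n_points: int = 5,
    rules: list[QuadratureRule] | None = None,
    center_rtol: float = 1e-9,
) -> DesignMatrix:
    """Build the n(N-1)+1 one-at-a-time design with shared nominal.

    Requires every rule's centre node to coincide with the parameter's
    nominal (odd N with a symmetric or log-symmetric family); otherwise
    the shared-nominal reduction is impossible and a DesignError is
    raised.
    """
    if rules is None:
        rules = [quadrature_rule(p, n_points) for p in params]
    nominal = {p.name: float(p.nominal) for p in params}
    for p, rule in zip(params, rules):
        c = rule.nodes[rule.center_index]
        scale = max(abs(c), abs(nominal[p.name]), 1.0)
        if n_points % 2 == 0 or abs(c - nominal[p.name]) > center_rtol * scale:
            raise DesignError(
                f"{p.name}: centre node {c!r} does not coincide with nominal "
                f"{nominal[p.name]!r}; the shared-nominal n(N-1)+1 design is "
                "impossible (use a full nN design instead)"
            )
    rows = []
    rows.append({"run_id": "run_000", "label": "nominal", **nominal})
    idx = 1
    for p, rule in zip(params, rules):
        for j in range(rule.n_points):
            if j == rule.center_index:
                continue
            row = dict(nominal)
            row[p.name] = float(rule.nodes[j])
            rows.append(
                {"run_id": f"run_{idx:03d}", "label": f"{p.name}:P{j + 1}", **row}
            )
            idx += 1
    runs = pd.DataFrame(rows, columns=["run_id", "label"] + [p.name for p in params])
    return DesignMatrix(
        runs=runs, parameters=tuple(p.name for p in params), n_points=n_points
    )


def _cut_outputs(
    outputs: dict[str, float] | pd.Series,
    design: DesignMatrix,
    rule: QuadratureRule,
    parameter: str,
) -> np.ndarray:
    """Outputs along one parameter's cut, nominal reused at the centre."""
    if isinstance(outputs, pd.Series):
        outputs = outputs.to_dict()
    by_label = dict(zip(design.runs["label"], design.runs["run_id"]))
    h = np.empty(rule.n_points)
    for j in range(rule.n_points):
        if j == rule.center_index:
            label = "nominal"
        else:
            label = f"{parameter}:P{j + 1}"
        run_id = by_label.get(label)
        if run_id is None or run_id not in outputs:
            raise KeyError(f"missing output for design run {label!r}")
        h[j] = float(outputs[run_id])
    return h


def mdrm_moments(
    outputs: dict[str, float] | pd.Series,
    design: DesignMatrix,
    rules: list[QuadratureRule],
) -> pd.DataFrame:
    """Per-parameter approximate mean rho and mean square theta.

    ``outputs`` maps run_id -> metric value.  Returns a DataFrame
    indexed by parameter with columns rho, theta.
    """
    rows = {}
    for rule in rules:
        h = _cut_outputs(outputs, design, rule, rule.parameter)
        rho = float(np.dot(rule.weights, h))
        theta = float(np.dot(rule.weights, h**2))
        rows[rule.parameter] = {"rho": rho, "theta": theta}
    return pd.DataFrame.from_dict(rows, orient="index").loc[list(design.parameters)]


@dataclass(frozen=True)
class SensitivityResult:
    """Primary sensitivity indices for one metric."""

    metric: str
    parameters: tuple[str, ...]
    rho: np.ndarray
    theta: np.ndarray
    S: np.ndarray
    h0: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rho": self.rho, "theta": self.theta, "S": self.S},
            index=list(self.parameters),
        )


def sensitivity_indices(
    moments: pd.DataFrame, h0: float, metric: str = "output"
) -> SensitivityResult:
    """Normalized primary sensitivity indices from M-DRM moments.

    S_i = (theta_i / rho_i^2 - 1) / sum_k (theta_k / rho_k^2 - 1).
    Parameters contributing no variance get S_i = 0.  If every
    contribution is zero the result is all-NaN with a warning.  A zero
    rho_i makes the ratio undefined and raises.
    """
    rho = moments["rho"].to_numpy(dtype=float)
    theta = moments["theta"].to_numpy(dtype=float)
    if np.any(rho == 0):
        bad = [p for p, r in zip(moments.index, rho) if r == 0]
        raise ZeroDivisionError(
            f"rho is zero for {bad}; the multiplicative ratio theta/rho^2 is "
            "undefined (metric changes sign around the cut-point?)"
        )
    contrib = theta / rho**2 - 1.0
    # Jensen guarantees theta >= rho^2; clip round-off negatives.
    contrib = np.where(contrib < 0, np.where(contrib > -1e-9, 0.0, contrib), contrib)
    if np.any(contrib < 0):
        raise ValueError("theta < rho^2 beyond round-off; inconsistent moments")
    total = contrib.sum()
    if total <= 0:
        warnings.warn(
            f"{metric}: all variance contributions are zero; indices undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        S = np.full_like(contrib, np.nan)
    else:
        S = contrib / total
    return SensitivityResult(
        metric=metric,
        parameters=tuple(moments.index),
        rho=rho,
        theta=theta,
        S=S,
        h0=float(h0),
    )


def mdrm_approximate(
    h0: float,
    design: DesignMatrix,
    rules: list[QuadratureRule],
    outputs: dict[str, float] | pd.Series,
):
    """Multiplicative surrogate hhat(x) = h0^(1-n) prod_i f_i(x_i).

    Each univariate factor f_i interpolates the evaluated cut outputs
    with a monotone piecewise cubic (no overshoot between nodes) and is
    held constant beyond the extreme nodes.  Exact at the cut-point.
    """
    if h0 == 0:
        raise ZeroDivisionError("h0 must be nonzero for the multiplicative form")
    factors = []
    for rule in rules:
        h = _cut_outputs(outputs, design, rule, rule.parameter)
        interp = PchipInterpolator(rule.nodes, h, extrapolate=False)
        lo, hi = rule.nodes[0], rule.nodes[-1]
        hlo, hhi = h[0], h[-1]

        def f(x, interp=interp, lo=lo, hi=hi, hlo=hlo, hhi=hhi):
            x = np.asarray(x, dtype=float)
            y = interp(np.clip(x, lo, hi))
            return np.where(x <= lo, hlo, np.where(x >= hi, hhi, y))

        factors.append(f)
    n = len(rules)

    def hhat(x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        prod = np.ones(x.shape[0]) * h0 ** (1 - n)
        for i, f in enumerate(factors):
            prod = prod * f(x[:, i])
        return prod if prod.size > 1 else float(prod[0])

    return hhat


# ---------------------------------------------------------------------------
# Model / Results interface


class MDRMSensitivity:
    """M-DRM sensitivity model over a design and its evaluated outputs.

    Parameters
    ----------
    outputs : DataFrame indexed by run_id with one column per metric
        (or a mapping run_id -> value for a single metric).
    design : the one-at-a-time DesignMatrix the outputs were evaluated on.
    rules : per-parameter quadrature rules matching the design.
    """

    def __init__(
        self,
        outputs,
        design: DesignMatrix,
        rules: list[QuadratureRule],
    ) -> None:
        if isinstance(outputs, dict):
            outputs = pd.DataFrame({"output": pd.Series(outputs)})
        elif isinstance(outputs, pd.Series):
            outputs = outputs.to_frame(outputs.name or "output")
        self.outputs = outputs
        self.design = design
        self.rules = list(rules)
        rule_params = tuple(r.parameter for r in self.rules)
        if rule_params != tuple(design.parameters):
            raise ValueError("rules must match design parameters in order")

    def fit(self) -> "MDRMResults":
        nominal_id = self.design.runs.loc[
            self.design.runs["label"] == "nominal", "run_id"
        ].iloc[0]
        results = {}
        moments = {}
        for metric in self.outputs.columns:
            col = self.outputs[metric]
            mom = mdrm_moments(col, self.design, self.rules)
            h0 = float(col.loc[nominal_id])
            results[metric] = sensitivity_indices(mom, h0, metric=metric)
            moments[metric] = mom
        return MDRMResults(self, results, moments)


class MDRMResults:
    """Fitted primary sensitivity indices for every metric."""

    def __init__(
        self,
        model: MDRMSensitivity,
        results: dict[str, SensitivityResult],
        moments: dict[str, pd.DataFrame],
    ) -> None:
        self.model = model
        self._results = results
        self._moments = moments

    @property
    def metrics(self) -> tuple[str, ...]:
        return tuple(self._results)

    def __getitem__(self, metric: str) -> SensitivityResult:
        return self._results[metric]

    @property
    def indices(self) -> pd.DataFrame:
        """Parameters x metrics table of primary sensitivity indices."""
        return pd.DataFrame({m: r.S for m, r in self._results.items()},
                            index=list(self.model.design.parameters))

    def influential(self, metric: str, threshold: float = 1.0 / 7.0) -> list[str]:
        from .metrics import influential as _influential

        return _influential(self._results[metric], threshold)

    def summary(self) -> str:
        lines = ["M-DRM primary sensitivity indices", "=" * 64]
        n = self.model.design.n_runs
        lines.append(
            f"parameters: {len(self.model.design.parameters)}   "
            f"Gauss points: {self.model.design.n_points}   runs: {n}"
        )
        ind = self.indices
        lines.append("")
        lines.append(ind.to_string(float_format=lambda v: f"{v:8.4f}"))
        lines.append("")
        for m, r in self._results.items():
            total = np.nansum(r.S)
            lines.append(f"{m}: h0 = {r.h0:.4g}, sum(S) = {total:.6f}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        import json

        payload = {
            m: {
                p: {
                    "rho": float(r.rho[i]),
                    "theta": float(r.theta[i]),
                    "S": float(r.S[i]),
                }
                for i, p in enumerate(r.parameters)
            }
            for m, r in self._results.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
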