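"""Rate-constant estimation from observable time series.

Selected rate constants are optimized in log10 space (they span many orders
of magnitude) by bounded least squares against tidy observable data, with
optional per-point standard deviations as weights.  Multi-start local
optimization: the first start is the table value (or mid-bounds), further
starts are drawn log-uniformly within the bounds from a seeded generator,
so a fixed seed gives a bit-reproducible result.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize

from .network import build_network, _parse_param_key, ConfigurationError
from .observables import predict_observable
from .sensitivity import relative_residual
from .simulate import Scenario, simulate, IntegrationError

__all__ = ["FitProblem", "FitResult", "FitError", "fit_rate_constants",
           "profile_loss"]


class FitError(RuntimeError):
    """All optimization starts failed."""


@dataclass
class FitProblem:
    """A bounded least-squares problem over selected rate constants.

    ``free_params`` use the override key syntax (int for forward, ``"13r"``
    for reverse).  ``data`` is tidy with columns ``time_min``, ``observable``,
    ``value`` (uM) and optionally ``sd``.  Default bounds are the table value
    times 10**+-3.  ``loss`` is ``"ssq"`` (weighted sum of squares) or
    ``"relres"`` (the sensitivity module's relative residual).
    """

    free_params: Sequence
    data: pd.DataFrame
    scenario: Scenario
    bounds: Mapping | None = None
    loss: str = "ssq"

    def __post_init__(self):
        if len(self.data) == 0:
            raise ValueError("data is empty")
        if self.loss not in ("ssq", "relres"):
            raise ValueError(f"unknown loss {self.loss!r}")
        net = build_network(self.scenario.ph, overrides=self.scenario.overrides)
        self._keys = []
        self._table_values = {}
        self._bounds = {}
        user_bounds = dict(self.bounds or {})
        for key in self.free_params:
            rid, direction = _parse_param_key(key)
            norm = f"{rid}{direction}"
            k_table = net.k(rid) if direction == "f" else net.k_rev(rid)
            self._keys.append(norm)
            self._table_values[norm] = k_table
            lo, hi = user_bounds.get(key, user_bounds.get(
                norm, (k_table * 1e-3, k_table * 1e3)))
            if not (0 < lo < hi):
                raise ValueError(f"bounds for {norm} must be positive and ordered")
            self._bounds[norm] = (lo, hi)

    def param_keys(self) -> list[str]:
        return list(self._keys)

    def table_value(self, key: str) -> float:
        return self._table_values[key]

    def bound(self, key: str) -> tuple[float, float]:
        return self._bounds[key]


@dataclass
class FitResult:
    estimates: dict[str, float]
    loss_value: float
    converged: bool
    n_evals: int
    seed: int
    flat_params: list[str] = field(default_factory=list)

    def to_json(self, problem: FitProblem | None = None) -> str:
        doc = {
            "estimates": self.estimates, "loss_value": self.loss_value,
            "converged": self.converged, "n_evals": self.n_evals,
            "seed": self.seed, "flat_params": self.flat_params,
        }
        if problem is not None:
            net = build_network(problem.scenario.ph,
                                overrides=problem.scenario.overrides)
            doc["network_hash"] = net.content_hash()
            doc["data_checksum"] = hashlib.sha256(
                problem.data.to_csv(index=False).encode()).hexdigest()[:16]
        return json.dumps(doc, indent=1)


def _data_vectors(data: pd.DataFrame):
    d = data.copy()
    if "sd" not in d.columns:
        d["sd"] = np.nan
    agg = (d.groupby(["observable", "time_min"], as_index=False)
           .agg(value=("value", "mean"), sd=("sd", "mean")))
    groups = {}
    for name, sub in agg.groupby("observable"):
        sub = sub.sort_values("time_min")
        groups[name] = (sub["time_min"].to_numpy() * 60.0,
                        sub["value"].to_numpy() * 1e-6,
                        sub["sd"].to_numpy() * 1e-6)
    return groups


def _residual_vector(problem: FitProblem, overrides: dict, groups) -> np.ndarray:
    all_times = sorted({t for ts, _, _ in groups.values() for t in ts})
    sc = problem.scenario.with_overrides(overrides)
    sc = replace(sc, sample_times=tuple(all_times))
    traj = simulate(sc)
    res = []
    for name, (ts, vals, sds) in groups.items():
        pred = predict_observable(traj, name, ts)
        if problem.loss == "relres":
            res.append((pred - vals) / np.abs(vals))
        else:
            w = np.where(np.isfinite(sds) & (sds > 0), sds, 1e-6)  # M
            res.append((pred - vals) / w)
    return np.concatenate(res)


def fit_rate_constants(problem: FitProblem, seed: int = 0,
                       n_starts: int = 1) -> FitResult:
    """Best local fit over ``n_starts`` seeded starts in log10-k space."""
    groups = _data_vectors(problem.data)
    keys = problem.param_keys()
    rng = np.random.default_rng(seed)

    def make_params(start: dict[str, float]) -> Parameters:
        params = Parameters()
        for key in keys:
            lo, hi = problem.bound(key)
            params.add(f"log10_{key}", value=np.log10(start[key]),
                       min=np.log10(lo), max=np.log10(hi))
        return params

    def residual(params) -> np.ndarray:
        overrides = {key: 10 ** params[f"log10_{key}"].value for key in keys}
        try:
            return _residual_vector(problem, overrides, groups)
        except IntegrationError:
            # steer the optimizer away from pathological corners
            n = sum(len(ts) for ts, _, _ in groups.values())
            return np.full(n, 1e6)

    starts = []
    first = {}
    for key in keys:
        lo, hi = problem.bound(key)
        k0 = problem.table_value(key)
        first[key] = k0 if lo <= k0 <= hi else np.sqrt(lo * hi)
    starts.append(first)
    for _ in range(n_starts - 1):
        starts.append({key: 10 ** rng.uniform(*np.log10(problem.bound(key)))
                       for key in keys})

    best = None
    n_evals = 0
    for start in starts:
        try:
            out = minimize(residual, make_params(start), method="least_squares")
        except Exception:
            continue
        n_evals += out.nfev
        loss = float(np.sum(np.asarray(out.residual) ** 2))
        if best is None or loss < best[0]:
            best = (loss, out)
    if best is None:
        raise FitError("all optimization starts failed")
    loss, out = best
    estimates = {key: float(10 ** out.params[f"log10_{key}"].value) for key in keys}

    # flat-loss diagnostic: a parameter whose half-decade perturbation leaves
    # the loss unchanged never fired in this scenario
    flat = []
    base_res = residual(out.params)
    base_loss = float(np.sum(base_res ** 2))
    for key in keys:
        pert = make_params({k: estimates[k] for k in keys})
        lo, hi = problem.bound(key)
        bumped = min(estimates[key] * 10 ** 0.5, hi)
        if bumped == estimates[key]:
            bumped = max(estimates[key] * 10 ** -0.5, lo)
        pert[f"log10_{key}"].value = np.log10(bumped)
        d_loss = abs(float(np.sum(residual(pert) ** 2)) - base_loss)
        if d_loss <= 1e-12 * (1.0 + base_loss):
            flat.append(key)
    return FitResult(estimates=estimates, loss_value=base_loss,
                     converged=bool(getattr(out, "success", True)),
                     n_evals=n_evals, seed=seed, flat_params=flat)


def profile_loss(problem: FitProblem, param, grid: Sequence[float],
                 reoptimize: bool = False, seed: int = 0) -> pd.DataFrame:
    """Loss along a grid for one parameter; others fixed or re-optimized.

    Returns a frame with columns ``k``, ``loss``, ``ok``; grid points where
    the model cannot be evaluated are flagged rather than fatal.
    """
    rid, direction = _parse_param_key(param)
    key = f"{rid}{direction}"
    if key not in problem.param_keys():
        raise ValueError(f"{key} is not a free parameter of this problem")
    groups = _data_vectors(problem.data)
    others = [k for k in problem.param_keys() if k != key]
    rows = []
    for k_val in grid:
        overrides = {key: float(k_val)}
        try:
            if reoptimize and others:
                sub = FitProblem(
                    free_params=others, data=problem.data,
                    scenario=problem.scenario.with_overrides(overrides),
                    bounds={k: problem.bound(k) for k in others},
                    loss=problem.loss)
                res = fit_rate_constants(sub, seed=seed)
                rows.append((float(k_val), res.loss_value, True))
            else:
                fixed = {k: problem.table_value(k) for k in others}
                fixed.update(overrides)
                r = _residual_vector(problem, fixed, groups)
                rows.append((float(k_val), float(np.sum(r ** 2)), True))
        except (IntegrationError, FitError):
            rows.append((float(k_val), np.nan, False))
    return pd.DataFrame(rows, columns=["k", "loss", "ok"])
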