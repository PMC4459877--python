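"""Dose-response analysis: normalization, D37 estimation, model comparison.

The observable is the *sprout elongation rate*: the mean sprout length of
an irradiated dish divided by the unirradiated control mean (a survival
proxy on [0, ~1.2] — values above 1 are real measurement scatter and are
kept). Under the k-hit target model the expected rate at dose ``D`` is

    rate(D) = S_k(x_k * D / D37)

where ``S_k`` is the Poisson CDF at k and ``x_k`` the mean hit number at
which ``S_k`` crosses exp(-1) (so every curve passes through ~37% at D37
regardless of k; comparisons between k values isolate curve *shape*).

Three D37 estimators are provided:

``loglinear_origin`` (default)
    Least squares of ln(rate) on dose through the origin; for k = 0 the
    slope is -1/D37 in closed form, for k >= 1 the same log-scale loss is
    minimized numerically.
``nonlinear_ls``
    Least squares of rate = S_k(x_k D / D37) on the rate scale.
``linear_crossing``
    Piecewise-linear interpolation of ln(rate) against dose, solved where
    it crosses ln(exp(-1)) = -1; the last segment is extrapolated when the
    observed rates never fall that low (the ``extrapolated`` flag records
    this). The estimate does not depend on k.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .hitmodel import (
    SURVIVAL_AT_D37,
    HitModelSpec,
    KLike,
    _as_k,
    d37_to_volume,
    k_hit_threshold,
    survival_probability,
)
from .physics import DEFAULT_PHYSICS, TargetGeometry, TargetPhysics

METHODS = ("loglinear_origin", "nonlinear_ls", "linear_crossing")


class DoseResponseError(ValueError):
    """Raised when a dose-response table cannot be normalized or fitted."""


@dataclass(frozen=True)
class DoseResponseTable:
    """One group's dose-response records.

    ``doses`` are sorted strictly increasing and must include a single
    dose-0 control. Either raw ``mean_lengths`` (mm) or pre-normalized
    ``rates`` (fractions; 1.0 at dose 0 after :func:`normalize`) may be
    present.
    """

    group_id: str
    doses: np.ndarray
    mean_lengths: Optional[np.ndarray] = None
    rates: Optional[np.ndarray] = None
    n_beans: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        order = np.argsort(doses)
        doses = doses[order]
        object.__setattr__(self, "doses", doses)
        for name in ("mean_lengths", "rates", "n_beans"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)[order]
                if arr.shape != doses.shape:
                    raise DoseResponseError(
                        f"group {self.group_id!r}: {name} has {arr.size} entries "
                        f"for {doses.size} doses"
                    )
                object.__setattr__(self, name, arr)
        if doses.size == 0:
            raise DoseResponseError(f"group {self.group_id!r}: no records")
        if np.any(doses < 0):
            raise DoseResponseError(f"group {self.group_id!r}: negative dose")
        if np.any(np.diff(doses) <= 0):
            raise DoseResponseError(f"group {self.group_id!r}: duplicate doses")
        if doses[0] != 0.0:
            raise DoseResponseError(
                f"group {self.group_id!r}: missing dose-0 control record"
            )
        if self.mean_lengths is not None and np.any(self.mean_lengths < 0):
            raise DoseResponseError(f"group {self.group_id!r}: negative mean length")
        if self.mean_lengths is None and self.rates is None:
            raise DoseResponseError(
                f"group {self.group_id!r}: need mean_lengths or rates"
            )

    @property
    def is_normalized(self) -> bool:
        return self.rates is not None and self.rates[0] == 1.0

    def to_frame(self) -> pd.DataFrame:
        data = {"group": self.group_id, "dose_gy": self.doses}
        if self.mean_lengths is not None:
            data["mean_length_mm"] = self.mean_lengths
        if self.n_beans is not None:
            data["n_beans"] = self.n_beans.astype(int)
        if self.rates is not None:
            data["rate_percent"] = self.rates * 100.0
        return pd.DataFrame(data)


def normalize(table: DoseResponseTable) -> DoseResponseTable:
    """Divide each dose's mean length by the control mean (idempotent).

    The control (dose 0) rate is exactly 1 afterwards; rates above 1 are
    retained. Raises :class:`DoseResponseError`, naming the group, when
    the control is missing or has zero mean length.
    """
    if table.mean_lengths is not None:
        control = table.mean_lengths[0]
        if control <= 0:
            raise DoseResponseError(
                f"group {table.group_id!r}: control mean length is {control}, "
                "cannot normalize"
            )
        rates = table.mean_lengths / control
    else:
        control = table.rates[0]
        if control <= 0:
            raise DoseResponseError(
                f"group {table.group_id!r}: control rate is {control}, cannot normalize"
            )
        rates = table.rates / control
    rates = rates.copy()
    rates[0] = 1.0
    return replace(table, rates=rates)


@dataclass(frozen=True)
class FitResult:
    """A fitted D37 with its implied target geometry and diagnostics."""

    group_id: str
    d37_gy: float
    geometry: TargetGeometry
    method: str
    hits_tolerated: int
    extrapolated: bool
    residual_ss: float
    n_points: int
    n_dropped: int = 0


def predict_curve(
    d37_gy: float, spec: KLike, doses: Sequence[float]
) -> np.ndarray:
    """Theoretical elongation/survival rates at the given doses.

    For k = 0 this is ``exp(-D/D37)``; for k >= 1 the mean-hit axis is
    scaled by the k-hit threshold so the curve still passes through
    exp(-1) at D37.
    """
    if not (d37_gy > 0):
        raise DoseResponseError(f"d37_gy must be positive, got {d37_gy!r}")
    doses = np.asarray(doses, dtype=float)
    k = _as_k(spec)
    if k == 0:
        return np.exp(-doses / d37_gy)
    x_k = k_hit_threshold(k).threshold
    means = x_k * doses / d37_gy
    return np.array([survival_probability(m, k) for m in means])


def _positive_rate_points(table: DoseResponseTable):
    """Positive-dose points with rate > 0; warns about dropped rates."""
    doses = table.doses[1:]
    rates = table.rates[1:]
    keep = rates > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"group {table.group_id!r}: dropping {n_dropped} non-positive rate(s) "
            "for log-scale fitting",
            stacklevel=3,
        )
    return doses[keep], rates[keep], n_dropped


def _loglinear_slope(doses: np.ndarray, rates: np.ndarray, group_id: str) -> float:
    logr = np.log(rates)
    slope = float(np.dot(doses, logr) / np.dot(doses, doses))
    if slope >= 0:
        raise DoseResponseError(
            f"group {group_id!r}: no decay detectable (rates non-decreasing in dose)"
        )
    return slope


def _fit_loglinear(table: DoseResponseTable, k: int):
    doses, rates, n_dropped = _positive_rate_points(table)
    if doses.size < 2:
        raise DoseResponseError(
            f"group {table.group_id!r}: need at least 2 positive non-control rates"
        )
    slope = _loglinear_slope(doses, rates, table.group_id)
    d37 = -1.0 / slope
    if k > 0:
        d37 = _refine_least_squares(doses, np.log(rates), k, d37, log_scale=True)
    return d37, doses.size, n_dropped


def _fit_nonlinear(table: DoseResponseTable, k: int):
    doses = table.doses[1:]
    rates = table.rates[1:]
    if doses.size < 2:
        raise DoseResponseError(
            f"group {table.group_id!r}: need at least 2 non-control doses"
        )
    pos_d, pos_r, _ = _positive_rate_points(table)
    if pos_d.size < 2:
        raise DoseResponseError(
            f"group {table.group_id!r}: need at least 2 positive non-control rates"
        )
    d37_0 = -1.0 / _loglinear_slope(pos_d, pos_r, table.group_id)
    d37 = _refine_least_squares(doses, rates, k, d37_0, log_scale=False)
    return d37, doses.size, 0


def _refine_least_squares(
    doses: np.ndarray, target: np.ndarray, k: int, d37_0: float, log_scale: bool
) -> float:
    def curve(d37: float) -> np.ndarray:
        return predict_curve(d37, k, doses)

    def resid(theta: np.ndarray) -> np.ndarray:
        pred = curve(math.exp(theta[0]))
        if log_scale:
            return np.log(np.maximum(pred, 1e-300)) - target
        return pred - target

    sol = optimize.least_squares(
        resid, x0=[math.log(d37_0)], xtol=1e-15, ftol=1e-15, gtol=1e-15
    )
    return float(math.exp(sol.x[0]))


def _fit_crossing(table: DoseResponseTable, k: int):
    # polyline through (0, ln 1) and the positive-rate points, solved at -1
    doses, rates, n_dropped = _positive_rate_points(table)
    if doses.size < 2:
        raise DoseResponseError(
            f"group {table.group_id!r}: need at least 2 positive non-control rates"
        )
    d = np.concatenate([[0.0], doses])
    y = np.concatenate([[0.0], np.log(rates)]) + 1.0  # zero at the crossing
    for i in range(d.size - 1):
        if y[i] > 0 >= y[i + 1]:
            frac = y[i] / (y[i] - y[i + 1])
            return float(d[i] + frac * (d[i + 1] - d[i])), doses.size, n_dropped
    slope = (y[-1] - y[-2]) / (d[-1] - d[-2])
    if slope >= 0:
        raise DoseResponseError(
            f"group {table.group_id!r}: no decay detectable in the final segment, "
            "cannot extrapolate to the 37% crossing"
        )
    return float(d[-1] - y[-1] / slope), doses.size, n_dropped


_FITTERS = {
    "loglinear_origin": _fit_loglinear,
    "nonlinear_ls": _fit_nonlinear,
    "linear_crossing": _fit_crossing,
}


def estimate_d37(
    table: DoseResponseTable,
    method: str = "loglinear_origin",
    hits_tolerated: KLike = 0,
    physics: TargetPhysics = DEFAULT_PHYSICS,
) -> FitResult:
    """Estimate D37 for one group and derive its target geometry.

    ``table`` is normalized first if raw lengths are present. The
    ``extrapolated`` flag is set when every observed rate stays above
    exp(-1), i.e. the 37% level was never reached on the dose grid.
    """
    if method not in _FITTERS:
        raise DoseResponseError(
            f"unknown method {method!r}; choose one of {METHODS}"
        )
    k = _as_k(hits_tolerated)
    if not table.is_normalized:
        table = normalize(table)
    d37, n_points, n_dropped = _FITTERS[method](table, k)
    if not (d37 > 0) or not math.isfinite(d37):
        raise DoseResponseError(
            f"group {table.group_id!r}: {method} produced invalid D37 {d37!r}"
        )
    pred = predict_curve(d37, k, table.doses)
    residual_ss = float(np.sum((table.rates - pred) ** 2))
    return FitResult(
        group_id=table.group_id,
        d37_gy=d37,
        geometry=d37_to_volume(physics, d37),
        method=method,
        hits_tolerated=k,
        extrapolated=bool(np.min(table.rates) > SURVIVAL_AT_D37),
        residual_ss=residual_ss,
        n_points=n_points,
        n_dropped=n_dropped,
    )


@dataclass(frozen=True)
class ModelComparison:
    """Side-by-side k = 0 and k = 1 fits of one dose-response table."""

    group_id: str
    fits: Dict[int, FitResult]
    curve_predictions: Dict[int, np.ndarray]
    preferred: HitModelSpec
    shoulder: bool

    @property
    def preferred_k(self) -> int:
        return self.preferred.hits_tolerated


def compare_models(
    table: DoseResponseTable,
    method: str = "loglinear_origin",
    physics: TargetPhysics = DEFAULT_PHYSICS,
) -> ModelComparison:
    """Fit the no-hit (k=0) and no+one-hit (k=1) models and rank them.

    The preferred model is the one with the lower residual sum of squares
    on the rate scale. ``shoulder`` reports whether the data show the
    low-dose plateau characteristic of multi-hit survival: the k = 1 fit
    describes the observations below its fitted D37 better than the k = 0
    fit does.
    """
    if not table.is_normalized:
        table = normalize(table)
    fits: Dict[int, FitResult] = {}
    preds: Dict[int, np.ndarray] = {}
    for k in (0, 1):
        fit = estimate_d37(table, method=method, hits_tolerated=k, physics=physics)
        fits[k] = fit
        preds[k] = predict_curve(fit.d37_gy, k, table.doses)
    preferred_k = min(fits, key=lambda k: fits[k].residual_ss)
    low = table.doses < fits[1].d37_gy
    low_ss = {k: float(np.sum((table.rates[low] - preds[k][low]) ** 2)) for k in (0, 1)}
    shoulder = low_ss[1] < low_ss[0]
    return ModelComparison(
        group_id=table.group_id,
        fits=fits,
        curve_predictions=preds,
        preferred=HitModelSpec(preferred_k),
        shoulder=shoulder,
    )


class HitTargetModel:
    """Poisson hit-target model for one group's dose-response data.

    Parameters
    ----------
    doses : array-like
        Doses in Gy, including the dose-0 control.
    lengths : array-like, optional
        Per-dose mean sprout lengths (mm); normalized internally.
    rates : array-like, optional
        Pre-normalized elongation rates as fractions (alternative to
        ``lengths``).
    group_id : str
        Label used in results and error messages.
    physics : TargetPhysics
        Energy-per-hit and density used to convert D37 into geometry.

    Examples
    --------
    >>> model = HitTargetModel([0, 10, 100, 400], rates=[1.0, 0.99, 0.9, 0.67])
    >>> res = model.fit()
    >>> res.d37_gy  # doctest: +SKIP
    1007.3
    """

    def __init__(
        self,
        doses: Sequence[float],
        lengths: Optional[Sequence[float]] = None,
        rates: Optional[Sequence[float]] = None,
        group_id: str = "sample",
        physics: TargetPhysics = DEFAULT_PHYSICS,
    ) -> None:
        table = DoseResponseTable(
            group_id=group_id,
            doses=np.asarray(doses, dtype=float),
            mean_lengths=None if lengths is None else np.asarray(lengths, dtype=float),
            rates=None if rates is None else np.asarray(rates, dtype=float),
        )
        self.table = normalize(table)
        self.physics = physics

    @classmethod
    def from_table(
        cls, table: DoseResponseTable, physics: TargetPhysics = DEFAULT_PHYSICS
    ) -> "HitTargetModel":
        model = cls.__new__(cls)
        model.table = normalize(table)
        model.physics = physics
        return model

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        group_id: Optional[str] = None,
        physics: TargetPhysics = DEFAULT_PHYSICS,
    ) -> "HitTargetModel":
        """Build a model from a long-format frame for a single group.

        Expects ``dose_gy`` plus either ``mean_length_mm`` or
        ``rate_percent``; an optional ``group`` column selects/validates
        the group.
        """
        if "group" in frame.columns:
            groups = frame["group"].unique()
            if group_id is None:
                if len(groups) != 1:
                    raise DoseResponseError(
                        f"frame holds groups {list(groups)}; pass group_id to choose one"
                    )
                group_id = str(groups[0])
            frame = frame[frame["group"] == group_id]
        if "dose_gy" not in frame.columns:
            raise DoseResponseError("frame must have a 'dose_gy' column")
        doses = frame["dose_gy"].to_numpy(dtype=float)
        lengths = rates = None
        if "mean_length_mm" in frame.columns:
            lengths = frame["mean_length_mm"].to_numpy(dtype=float)
        elif "rate_percent" in frame.columns:
            rates = frame["rate_percent"].to_numpy(dtype=float) / 100.0
        else:
            raise DoseResponseError(
                "frame must have 'mean_length_mm' or 'rate_percent'"
            )
        return cls(
            doses, lengths=lengths, rates=rates,
            group_id=group_id or "sample", physics=physics,
        )

    @property
    def group_id(self) -> str:
        return self.table.group_id

    def fit(
        self, method: str = "loglinear_origin", hits_tolerated: KLike = 0
    ) -> "HitTargetResults":
        result = estimate_d37(
            self.table, method=method, hits_tolerated=hits_tolerated,
            physics=self.physics,
        )
        return HitTargetResults(self, result)

    def compare(self, method: str = "loglinear_origin") -> ModelComparison:
        return compare_models(self.table, method=method, physics=self.physics)


class HitTargetResults:
    """Results of a :class:`HitTargetModel` fit."""

    def __init__(self, model: HitTargetModel, result: FitResult) -> None:
        self.model = model
        self._result = result

    @property
    def d37_gy(self) -> float:
        return self._result.d37_gy

    @property
    def geometry(self) -> TargetGeometry:
        return self._result.geometry

    @property
    def volume_m3(self) -> float:
        return self._result.geometry.volume_m3

    @property
    def diameter_nm(self) -> float:
        return self._result.geometry.diameter_nm

    @property
    def method(self) -> str:
        return self._result.method

    @property
    def hits_tolerated(self) -> int:
        return self._result.hits_tolerated

    @property
    def extrapolated(self) -> bool:
        return self._result.extrapolated

    @property
    def residual_ss(self) -> float:
        return self._result.residual_ss

    @property
    def nobs(self) -> int:
        return self._result.n_points

    @property
    def fit_result(self) -> FitResult:
        return self._result

    def predict(self, doses: Optional[Sequence[float]] = None) -> np.ndarray:
        """Fitted elongation rates at ``doses`` (default: observed grid)."""
        if doses is None:
            doses = self.model.table.doses
        return predict_curve(self.d37_gy, self.hits_tolerated, doses)

    def summary(self) -> str:
        r = self._result
        phys = self.model.physics
        lines = [
            "Hit-target model fit",
            "=" * 44,
            f"group:            {r.group_id}",
            f"method:           {r.method}",
            f"hits tolerated:   {r.hits_tolerated}",
            f"n points (fit):   {r.n_points}"
            + (f"  ({r.n_dropped} dropped)" if r.n_dropped else ""),
            "-" * 44,
            f"D37 [Gy]:         {r.d37_gy:.6g}",
            f"target volume:    {r.geometry.volume_m3:.6g} m^3",
            f"target diameter:  {r.geometry.diameter_nm:.3g} nm",
            f"extrapolated:     {r.extrapolated}",
            f"residual SS:      {r.residual_ss:.6g}",
            "-" * 44,
            f"epsilon:          {phys.epsilon_j:g} J",
            f"rho:              {phys.rho_kg_m3:g} kg/m^3",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed rates and the fitted survival curve (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        table = self.model.table
        ax.plot(table.doses, table.rates, "o", label="observed")
        grid = np.linspace(0, table.doses.max(), 200)
        ax.plot(grid, self.predict(grid), "--",
                label=f"k={self.hits_tolerated} fit (D37={self.d37_gy:.3g} Gy)")
        ax.axhline(SURVIVAL_AT_D37, color="grey", lw=0.5)
        ax.set_xlabel("dose [Gy]")
        ax.set_ylabel("elongation rate")
        ax.set_title(table.group_id)
        ax.legend()
        return ax


def fit_tables(
    tables: Iterable[DoseResponseTable],
    method: str = "loglinear_origin",
    hits_tolerated: KLike = 0,
    physics: TargetPhysics = DEFAULT_PHYSICS,
) -> list:
    """Fit every group in ``tables``; returns a list of :class:`FitResult`."""
    return [
        estimate_d37(t, method=method, hits_tolerated=hits_tolerated, physics=physics)
        for t in tables
    ]
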