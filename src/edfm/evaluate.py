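"""Evaluation metrics, benchmark comparison arithmetic and logistic
parameter recovery.

The packaged benchmark fixture (``data/benchmark_rmse.csv``) is a
transcription of published organ-parameter prediction errors for this
model against WOFOST and two multimodal baselines; plant-height RMSE is
kept in mm as tabulated (one prose mention uses cm — the fixture
follows the table and the discrepancy is documented, not resolved).
:func:`comparison_report` recomputes the percent error reductions of
the closed-loop model against each baseline from those raw RMSEs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError, InvalidArgumentError, UndefinedMetricError
from .morphology import GrowthParams

logger = logging.getLogger(__name__)

__all__ = [
    "rmse",
    "r_squared",
    "nrmse",
    "percent_reduction",
    "load_benchmark_table",
    "comparison_report",
    "LogisticFit",
    "fit_logistic_growth",
]


def _pair(pred, obs) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float).ravel()
    o = np.asarray(obs, dtype=float).ravel()
    if p.shape != o.shape or len(p) < 1:
        raise InvalidArgumentError("pred and obs must be equal-length nonempty series")
    return p, o


def rmse(pred, obs) -> float:
    """Root mean square error sqrt(mean((pred - obs)^2))."""
    p, o = _pair(pred, obs)
    return float(np.sqrt(np.mean((p - o) ** 2)))


def r_squared(pred, obs) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    p, o = _pair(pred, obs)
    ss_tot = np.sum((o - o.mean()) ** 2)
    if ss_tot <= 0:
        raise UndefinedMetricError("R^2 undefined for constant observations")
    return float(1.0 - np.sum((p - o) ** 2) / ss_tot)


def nrmse(pred, obs) -> float:
    """RMSE normalized by the observation mean (range-normalization by flag upstream)."""
    p, o = _pair(pred, obs)
    if o.mean() == 0:
        raise UndefinedMetricError("NRMSE undefined for zero-mean observations")
    return rmse(p, o) / float(o.mean())


def percent_reduction(reference: float, candidate: float) -> float:
    """100 (reference - candidate) / reference; positive means improvement."""
    if reference <= 0:
        raise InvalidArgumentError("reference error must be positive")
    return 100.0 * (reference - candidate) / reference


def load_benchmark_table() -> pd.DataFrame:
    """Load the packaged benchmark RMSE fixture."""
    with resources.files("edfm").joinpath("data/benchmark_rmse.csv").open() as fh:
        return pd.read_csv(fh)


def comparison_report(table: pd.DataFrame | None = None, model: str = "EDFM") -> pd.DataFrame:
    """Percent reductions of the target model vs every baseline row.

    One row per (baseline, metric) with the reference and candidate
    RMSEs and the reduction, formatted to 1 decimal place in
    ``reduction_1dp``.
    """
    if table is None:
        table = load_benchmark_table()
    if model not in set(table["model"]):
        raise InvalidArgumentError(f"table has no row for model {model!r}")
    ours = table[table["model"] == model].iloc[0]
    rows = []
    for _, base in table[table["model"] != model].iterrows():
        for metric in ("height_rmse_mm", "lai_rmse_pct"):
            red = percent_reduction(float(base[metric]), float(ours[metric]))
            rows.append(
                {
                    "baseline": base["model"],
                    "metric": metric,
                    "reference": float(base[metric]),
                    "candidate": float(ours[metric]),
                    "reduction_pct": red,
                    "reduction_1dp": round(red, 1),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class LogisticFit:
    params: GrowthParams
    stderr: dict[str, float]
    residual_rmse: float
    identifiability_warning: bool


def _logistic(pdt, size_max, k, pdt_mid):
    return size_max / (1.0 + np.exp(-k * (pdt - pdt_mid)))


def fit_logistic_growth(pdt, size) -> LogisticFit:
    """Nonlinear least squares for (size_max, k, pdt_mid) on (PDT, L) data.

    Initialization: size_max0 = 1.05 max(L); pdt_mid0 = PDT at the
    half-max crossing; k0 from the slope of the log-linearized logit.
    Standard errors come from the fit covariance. Data that never reach
    half of the estimated asymptote set ``identifiability_warning`` (the
    asymptote is then poorly constrained, visible in its standard
    error).
    """
    x = np.asarray(pdt, dtype=float).ravel()
    y = np.asarray(size, dtype=float).ravel()
    if x.shape != y.shape or len(x) < 5:
        raise InvalidArgumentError("need >= 5 (PDT, L) points")
    lmax0 = 1.05 * float(y.max())
    if lmax0 <= 0:
        raise FitError("all observations nonpositive; nothing to fit")
    half = lmax0 / 2.0
    above = np.flatnonzero(y >= half)
    pdt_mid0 = float(x[above[0]]) if len(above) else float(x[-1])
    # log-linearized slope: logit(L/Lmax0) is linear in PDT with slope k
    frac = np.clip(y / lmax0, 1e-6, 1 - 1e-6)
    logit = np.log(frac / (1 - frac))
    slope = np.polyfit(x, logit, 1)[0]
    k0 = float(slope) if slope > 1e-6 else 0.1
    try:
        popt, pcov = curve_fit(
            _logistic, x, y, p0=[lmax0, k0, max(pdt_mid0, 1e-6)], maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(f"logistic fit did not converge: {exc}") from exc
    if popt[0] <= 0 or popt[1] <= 0:
        raise FitError(f"logistic fit produced invalid parameters {popt}")
    se = np.sqrt(np.abs(np.diag(pcov)))
    warn = bool(y.max() < popt[0] / 2.0)
    if warn:
        logger.warning(
            "observations never reach half the fitted asymptote; "
            "size_max is weakly identified (se=%.3g)", se[0],
        )
    resid = _logistic(x, *popt) - y
    return LogisticFit(
        params=GrowthParams(float(popt[0]), float(popt[1]), float(popt[2])),
        stderr={"size_max": float(se[0]), "k": float(se[1]), "pdt_mid": float(se[2])},
        residual_rmse=float(np.sqrt(np.mean(resid**2))),
        identifiability_warning=warn,
    )
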