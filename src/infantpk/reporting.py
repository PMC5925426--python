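"""Study-style summary outputs: parameter tables, individual clearances, regimen tables.

Descriptive conventions follow the source field: geometric means for
lognormal-ish quantities, CV% defaulting to 100·SD(log x) (the geometric CV
√(exp(s²)−1) is available as an option), medians and ranges as printed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .nlme import FitResult
from .regimens import SimulationSummary

__all__ = [
    "summarize_individual_cl",
    "individual_cl",
    "parameter_table",
    "regimen_table",
    "geometric_mean",
]


def geometric_mean(x) -> float:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(x))))


def _cv_pct(x, method: str) -> float:
    s = float(np.std(np.log(np.asarray(x, dtype=float)), ddof=1))
    if method == "sd_log":
        return 100.0 * s
    if method == "geometric":
        return 100.0 * np.sqrt(np.expm1(s * s))
    raise ValueError("cv method must be 'sd_log' or 'geometric'")


def summarize_individual_cl(
    values, grouping=None, cv_method: str = "sd_log"
) -> pd.DataFrame:
    """Descriptive statistics of per-subject apparent clearance by group.

    ``values`` is a sequence of CL/F values (L/h) or a DataFrame with columns
    ``CL`` and a grouping column named by ``grouping``. Returns one row per
    group with n, geometric mean, CV%, median and range.
    """
    if isinstance(values, pd.DataFrame):
        df = values
        groups = df.groupby(grouping) if grouping else [("all", df)]
        items = [(g, sub["CL"].to_numpy(dtype=float)) for g, sub in groups]
    else:
        items = [("all", np.asarray(values, dtype=float))]
    rows = []
    for g, x in items:
        rows.append(
            {
                "group": g,
                "n": int(x.size),
                "geometric_mean": geometric_mean(x),
                "cv_pct": _cv_pct(x, cv_method) if x.size > 1 else 0.0,
                "median": float(np.median(x)),
                "min": float(x.min()),
                "max": float(x.max()),
            }
        )
    return pd.DataFrame(rows)


def individual_cl(fit: FitResult, weights: pd.Series | dict) -> pd.DataFrame:
    """Empirical-Bayes individual clearances, absolute and per kg.

    CL/F_i = θ_cl · (W_i / reference)^exponent · exp(η̂_cl,i), using the
    fitted model's weight link (if any) and each subject's weight (kg),
    typically the PK-visit weight.
    """
    model = fit.model
    theta_cl = model.theta["cl"]
    link = next(
        (l for l in model.covariate_links if l.target == "cl" and l.covariate == "wt"),
        None,
    )
    weights = pd.Series(weights)
    eta = (
        fit.etas["cl"]
        if "cl" in getattr(fit.etas, "columns", [])
        else pd.Series(0.0, index=weights.index)
    )
    rows = []
    for sid, w in weights.items():
        tv = theta_cl * ((w / link.reference) ** link.exponent if link else 1.0)
        cl = tv * float(np.exp(eta.get(sid, 0.0)))
        rows.append({"ID": sid, "WT": w, "CL": cl, "CL_per_kg": cl / w})
    return pd.DataFrame(rows)


def parameter_table(fit: FitResult) -> pd.DataFrame:
    """Estimates with SE/RSE%/95% CI and CV% for variance components.

    CV% is reported as 100·√(variance) for ω² and the proportional σ²,
    the convention matching the printed population-PK tables this layout
    mirrors.
    """
    tab = fit.parameter_table()
    cv = []
    for name, est in zip(tab["parameter"], tab["estimate"]):
        if name.startswith(("omega2_", "sigma2_prop")):
            cv.append(100.0 * np.sqrt(est))
        else:
            cv.append(np.nan)
    tab["cv_pct"] = cv
    return tab


def regimen_table(summaries: list[SimulationSummary]) -> pd.DataFrame:
    """5th/50th/95th percentile Cmin and Cmax per regimen."""
    rows = []
    for s in summaries:
        row = {"regimen": s.regimen}
        for p in sorted(s.cmin):
            row[f"cmin_p{p:g}"] = s.cmin[p]
        for p in sorted(s.cmax):
            row[f"cmax_p{p:g}"] = s.cmax[p]
        rows.append(row)
    return pd.DataFrame(rows)
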