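"""Allometric covariate links and stepwise covariate selection.

Body weight is the covariate of interest in this infant population: the dose
is prescribed in mg/kg and weight is confounded with age, group and visit, so
it is the single candidate tested, through the allometric relation

    TVP_i = P_pop · (cov_i / cov_med) ** exponent

with the exponent either estimated or fixed at the theoretical values
(0.75 for clearance, 1 for volume). Selection follows the classical
forward-inclusion (ΔOFV ≥ 3.84, P < .05, df=1) / backward-deletion
(ΔOFV ≥ 6.64, P < .01) procedure, with free-versus-fixed exponent variants
compared by AIC because they are not nested.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .nlme import FitOptions, PopulationModel, aic, fit

__all__ = [
    "CovariateLink",
    "SelectionTrace",
    "allometric",
    "build_base_model",
    "build_final_model",
    "forward_backward_selection",
    "FORWARD_DELTA_OFV",
    "BACKWARD_DELTA_OFV",
    "REFERENCE_WEIGHT_KG",
]

FORWARD_DELTA_OFV = 3.84  # χ²(1) at P = .05
BACKWARD_DELTA_OFV = 6.64  # χ²(1) at P = .01
#: median body weight (kg) of the study population across all visits
REFERENCE_WEIGHT_KG = 6.3


@dataclass(frozen=True)
class CovariateLink:
    """An allometric covariate effect on one structural parameter."""

    target: str  # "cl" or "v"
    covariate: str = "wt"
    reference: float = REFERENCE_WEIGHT_KG
    exponent: float = 0.75
    estimate_exponent: bool = False

    def __post_init__(self) -> None:
        if self.reference <= 0:
            raise ValueError("covariate reference value must be > 0")

    @property
    def label(self) -> str:
        mode = "free" if self.estimate_exponent else f"fixed={self.exponent:g}"
        return f"{self.covariate}->{self.target} ({mode})"


@dataclass
class SelectionTrace:
    """Ordered record of every candidate fit made during selection."""

    steps: pd.DataFrame

    def to_csv(self, path) -> None:
        self.steps.to_csv(path, index=False)


def allometric(
    p_pop: float, cov: float | np.ndarray, cov_med: float, exponent: float
) -> float | np.ndarray:
    """Typical parameter value at covariate value ``cov``: P_pop·(cov/cov_med)^exponent."""
    return p_pop * (np.asarray(cov, dtype=float) / cov_med) ** exponent


def build_base_model() -> PopulationModel:
    """The structural base model with the published base-run estimates.

    One-compartment, first-order absorption/elimination, exponential
    between-subject variability on CL/F, V/F and ka, proportional residual
    error; no covariates.
    """
    return PopulationModel(
        theta={"cl": 19.9, "v": 137.0, "ka": 1.08},
        omega2={"cl": 0.238, "v": 0.0276, "ka": 2.40},
        sigma2_prop=0.0974,
        name="base",
    )


def build_final_model(reference_weight: float = REFERENCE_WEIGHT_KG) -> PopulationModel:
    """The published final model.

    CL/F = θ1·(weight/6.3)^0.75·exp(η1), V/F = θ2, ka = θ3·exp(η2),
    proportional residual error; θ1 = 19.3 L/h, θ2 = 122 L, θ3 = 0.993 1/h,
    ω²_CL = 0.195, ω²_ka = 1.75, σ² = 0.0953. The random effect on V/F is
    omitted (its confidence interval included 0 and its shrinkage was large).
    """
    return PopulationModel(
        theta={"cl": 19.3, "v": 122.0, "ka": 0.993},
        omega2={"cl": 0.195, "ka": 1.75},
        sigma2_prop=0.0953,
        covariate_links=(
            CovariateLink(
                target="cl",
                covariate="wt",
                reference=reference_weight,
                exponent=0.75,
            ),
        ),
        name="final",
    )


def default_candidates(reference: float = REFERENCE_WEIGHT_KG) -> list[CovariateLink]:
    """Weight on CL/F and on V/F, each as free-exponent and fixed variants."""
    return [
        CovariateLink("cl", "wt", reference, 0.75, estimate_exponent=False),
        CovariateLink("cl", "wt", reference, 0.75, estimate_exponent=True),
        CovariateLink("v", "wt", reference, 1.0, estimate_exponent=False),
        CovariateLink("v", "wt", reference, 1.0, estimate_exponent=True),
    ]


def _n_params(model: PopulationModel) -> int:
    n = len(model.theta) + len(model.omega2)
    n += int(model.sigma2_prop > 0) + int(model.sigma2_add > 0)
    n += len(model.omega_corr)
    n += sum(1 for l in model.covariate_links if l.estimate_exponent)
    return n


def forward_backward_selection(
    base_model: PopulationModel,
    candidates: list[CovariateLink],
    data,
    fit_options: FitOptions | None = None,
) -> tuple[PopulationModel, SelectionTrace]:
    """Stepwise covariate selection around a fitted base model.

    Step 1 (forward): each candidate link is added univariately; a link is
    significant when ΔOFV ≥ 3.84 (inclusive, df=1). When both the free- and
    fixed-exponent variants of the same (target, covariate) pair are
    significant, the variant with the lower AIC is retained (the variants are
    not nested). Step 2: all retained links enter a full model. Step 3
    (backward): links whose single deletion raises the OFV by < 6.64 are
    removed, smallest ΔOFV first, refitting after each removal.

    A candidate whose fit fails is marked untestable and selection continues.
    Deterministic given data and fit options.
    """
    fit_options = fit_options or FitOptions(compute_se=False)
    rows = []

    base_fit = fit(base_model, data, fit_options)
    ofv_base = base_fit.ofv
    rows.append(
        {
            "step": "base",
            "candidate": "-",
            "ofv": ofv_base,
            "delta_ofv": 0.0,
            "df": 0,
            "p": np.nan,
            "aic": aic(ofv_base, _n_params(base_model)),
            "decision": "reference",
        }
    )

    # step 1: univariate forward
    per_pair: dict[tuple, list] = {}
    for cand in candidates:
        m = replace(
            base_model,
            covariate_links=base_model.covariate_links + (cand,),
            theta=dict(base_fit.model.theta),
            omega2=dict(base_fit.model.omega2),
            sigma2_prop=base_fit.model.sigma2_prop,
            sigma2_add=base_fit.model.sigma2_add,
        )
        try:
            f = fit(m, data, fit_options)
        except Exception:
            rows.append(
                {
                    "step": "forward",
                    "candidate": cand.label,
                    "ofv": np.nan,
                    "delta_ofv": np.nan,
                    "df": np.nan,
                    "p": np.nan,
                    "aic": np.nan,
                    "decision": "untestable",
                }
            )
            continue
        df = 1  # the covariate effect tested on one parameter
        delta = ofv_base - f.ofv
        cand_aic = aic(f.ofv, _n_params(m))
        include = delta >= FORWARD_DELTA_OFV
        rows.append(
            {
                "step": "forward",
                "candidate": cand.label,
                "ofv": f.ofv,
                "delta_ofv": delta,
                "df": df,
                "p": float(np.nan) if delta < 0 else _chi2_p(delta, df),
                "aic": cand_aic,
                "decision": "include" if include else "reject",
            }
        )
        if include:
            per_pair.setdefault((cand.target, cand.covariate), []).append(
                (cand_aic, cand, f)
            )

    retained = []
    for pair, variants in per_pair.items():
        variants.sort(key=lambda t: t[0])
        best_aic, best_cand, best_fit_ = variants[0]
        # keep the fitted exponent of a free-exponent winner
        if best_cand.estimate_exponent:
            best_cand = best_fit_.model.covariate_links[-1]
        retained.append(best_cand)
        for a, c, _ in variants[1:]:
            rows.append(
                {
                    "step": "aic",
                    "candidate": c.label,
                    "ofv": np.nan,
                    "delta_ofv": np.nan,
                    "df": np.nan,
                    "p": np.nan,
                    "aic": a,
                    "decision": "reject (higher AIC)",
                }
            )

    if not retained:
        return base_fit.model, SelectionTrace(pd.DataFrame(rows))

    # step 2: full model with all retained links
    current = replace(base_model, covariate_links=base_model.covariate_links + tuple(retained))
    full_fit = fit(current, data, fit_options)
    ofv_current = full_fit.ofv
    rows.append(
        {
            "step": "full",
            "candidate": "+".join(l.label for l in retained),
            "ofv": ofv_current,
            "delta_ofv": ofv_base - ofv_current,
            "df": len(retained),
            "p": _chi2_p(max(ofv_base - ofv_current, 0.0), len(retained)),
            "aic": aic(ofv_current, _n_params(current)),
            "decision": "full model",
        }
    )
    current = full_fit.model

    # step 3: backward deletion
    while len(current.covariate_links) > len(base_model.covariate_links):
        deletions = []
        for link in current.covariate_links[len(base_model.covariate_links):]:
            reduced_links = tuple(l for l in current.covariate_links if l is not link)
            reduced = replace(current, covariate_links=reduced_links)
            try:
                rf = fit(reduced, data, fit_options)
            except Exception:
                continue
            delta = rf.ofv - ofv_current  # OFV increase on deletion
            deletions.append((delta, link, rf))
            rows.append(
                {
                    "step": "backward",
                    "candidate": link.label,
                    "ofv": rf.ofv,
                    "delta_ofv": delta,
                    "df": 1,
                    "p": _chi2_p(max(delta, 0.0), 1),
                    "aic": aic(rf.ofv, _n_params(reduced)),
                    "decision": "remove" if delta < BACKWARD_DELTA_OFV else "keep",
                }
            )
        removable = [d for d in deletions if d[0] < BACKWARD_DELTA_OFV]
        if not removable:
            break
        removable.sort(key=lambda t: t[0])
        _, _, rf = removable[0]
        current = rf.model
        ofv_current = rf.ofv

    return current, SelectionTrace(pd.DataFrame(rows))


def _chi2_p(delta: float, df: int) -> float:
    from scipy import stats

    return float(stats.chi2.sf(delta, df))
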