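"""Simulation-based model qualification: VPC, pcVPC and coverage statistics.

A visual predictive check re-simulates the complete study design (same
subjects, dose histories, occasion weights and sampling times) many times
from the model, then compares observed percentiles per bin with the
distribution of the same percentiles across simulated replicates. The
prediction-corrected variant rescales observations and simulations by the
bin-median population prediction, removing dose/covariate heterogeneity
within a bin. Percentiles use linear interpolation between order statistics
(numpy's default convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import StudyDataset
from .nlme import PopulationModel, SubjectData, individual_prediction, subjects_from_dataset

__all__ = ["VPCResult", "vpc", "pc_vpc", "coverage", "simulate_replicates"]


@dataclass
class VPCResult:
    """Per-bin observed and simulated percentile summaries."""

    table: pd.DataFrame
    n_replicates: int
    percentiles: tuple
    prediction_corrected: bool
    seed: object = None

    def __post_init__(self) -> None:
        t = self.table
        for stem in ("obs", "sim_med"):
            lo, md, hi = (f"{stem}_p{p:g}" for p in self.percentiles)
            bad = t[(t[lo] > t[md] + 1e-12) | (t[md] > t[hi] + 1e-12)]
            if len(bad):
                raise ValueError("percentile curves not ordered within a bin")


def _obs_frame(ds: StudyDataset) -> pd.DataFrame:
    """Usable observation rows in the same order subjects_from_dataset emits them."""
    frames = []
    for _, sub in ds.df.groupby("ID", sort=False):
        frames.append(sub[(sub["EVID"] == 0) & (sub["MDV"] == 0)])
    return pd.concat(frames)


def _sim_profiles_one_cpt(
    model: PopulationModel, sub: SubjectData, etas: np.ndarray
) -> np.ndarray:
    """(n_rep × n_obs) structural predictions for a matrix of η draws."""
    from .nlme import _typical_values

    vals = _typical_values(model, sub)
    names = model.eta_names
    nobs = sub.obs_times.size
    R = etas.shape[0]
    cl = np.broadcast_to(np.atleast_1d(vals["cl"]), (nobs,))[None, :] * np.ones((R, 1))
    v = np.full(R, float(np.mean(np.atleast_1d(vals["v"]))))
    ka = np.full(R, float(np.mean(np.atleast_1d(vals["ka"]))))
    if "cl" in names:
        cl = cl * np.exp(etas[:, names.index("cl")])[:, None]
    if "v" in names:
        v = v * np.exp(etas[:, names.index("v")])
    if "ka" in names:
        ka = ka * np.exp(etas[:, names.index("ka")])
    ke = cl / v[:, None]  # (R, nobs)
    dtp, active = sub._dt, sub._active  # (ndose, nobs)
    ka_b = ka[:, None, None]
    ke_b = ke[:, None, :]
    degen = np.abs(ka_b - ke_b) < 1e-8 * ka_b
    denom = np.where(degen, 1.0, ka_b - ke_b)
    term = ka_b / (v[:, None, None] * denom) * (
        np.exp(-ke_b * dtp[None]) - np.exp(-ka_b * dtp[None])
    )
    if degen.any():
        lim = ka_b * dtp[None] * np.exp(-ka_b * dtp[None]) / v[:, None, None]
        term = np.where(degen, lim, term)
    conc = (np.where(active[None], term, 0.0) * sub.dose_amounts[None, :, None]).sum(
        axis=1
    )
    return conc * 1000.0


def simulate_replicates(
    model: PopulationModel,
    subjects: list[SubjectData],
    n_replicates: int,
    rng: np.random.Generator,
    include_residual_error: bool = True,
) -> np.ndarray:
    """Simulate the whole design ``n_replicates`` times.

    Returns an (n_replicates × total_observations) array, columns ordered as
    the concatenation of each subject's observations.
    """
    omega = model.omega_matrix()
    cols = []
    for sub in subjects:
        if model.n_eta:
            etas = rng.multivariate_normal(
                np.zeros(model.n_eta), omega, size=n_replicates
            )
        else:
            etas = np.zeros((n_replicates, 0))
        if model.structural == "one_cpt_first_order" and not callable(model.structural):
            f = _sim_profiles_one_cpt(model, sub, etas)
        else:
            f = np.vstack(
                [individual_prediction(model, sub, e) for e in etas]
            )
        if include_residual_error:
            y = f.copy()
            if model.sigma2_prop:
                y = y * (
                    1.0 + rng.normal(0.0, np.sqrt(model.sigma2_prop), f.shape)
                )
            if model.sigma2_add:
                y = y + rng.normal(0.0, np.sqrt(model.sigma2_add), f.shape)
        else:
            y = f
        cols.append(y)
    return np.concatenate(cols, axis=1)


def _bin_keys(obs: pd.DataFrame, bins) -> pd.Series:
    if bins is None:
        return obs["VISIT"].astype(str) + "/TAD=" + obs["TAD"].astype(float).map("{:g}".format)
    if isinstance(bins, int):
        return pd.qcut(obs["TIME"], q=bins, duplicates="drop").astype(str)
    raise ValueError("bins must be None (nominal design bins) or an integer")


def _vpc_impl(
    model, dataset, n_replicates, bins, seed, percentiles, prediction_corrected
) -> VPCResult:
    rng = np.random.default_rng(seed)
    subjects = subjects_from_dataset(dataset)
    obs = _obs_frame(dataset)
    y = obs["DV"].to_numpy(dtype=float)
    sims = simulate_replicates(model, subjects, n_replicates, rng)
    keys = _bin_keys(obs, bins).to_numpy()

    if prediction_corrected:
        pred = np.concatenate(
            [individual_prediction(model, s, np.zeros(model.n_eta)) for s in subjects]
        )
        keep = np.ones(len(y), dtype=bool)
        scale = np.ones(len(y))
        for k in np.unique(keys):
            sel = keys == k
            if np.any(pred[sel] <= 0):
                warnings.warn(
                    f"bin {k} has a non-positive population prediction; excluded"
                )
                keep[sel] = False
                continue
            scale[sel] = np.median(pred[sel]) / pred[sel]
        y = y * scale
        sims = sims * scale[None, :]
        y, sims, keys = y[keep], sims[:, keep], keys[keep]

    rows = []
    for k in pd.unique(keys):
        sel = keys == k
        obs_p = np.percentile(y[sel], percentiles)
        sim_p = np.percentile(sims[:, sel], percentiles, axis=1)  # (3, R)
        row = {"bin": k, "n_obs": int(sel.sum())}
        for i, p in enumerate(percentiles):
            row[f"obs_p{p:g}"] = obs_p[i]
            row[f"sim_med_p{p:g}"] = float(np.median(sim_p[i]))
            row[f"sim_lo_p{p:g}"] = float(np.percentile(sim_p[i], 2.5))
            row[f"sim_hi_p{p:g}"] = float(np.percentile(sim_p[i], 97.5))
        rows.append(row)
    return VPCResult(
        table=pd.DataFrame(rows),
        n_replicates=n_replicates,
        percentiles=tuple(percentiles),
        prediction_corrected=prediction_corrected,
        seed=seed,
    )


def vpc(
    model: PopulationModel,
    dataset: StudyDataset,
    n_replicates: int = 1000,
    bins=None,
    seed=None,
    percentiles: tuple = (5, 50, 95),
) -> VPCResult:
    """Visual predictive check of ``model`` against ``dataset``.

    Simulates the full design ``n_replicates`` times with fresh η and ε draws
    and summarises observed and simulated percentiles per bin (default bins:
    nominal time-after-dose within visit). Deterministic given ``seed``.
    """
    return _vpc_impl(model, dataset, n_replicates, bins, seed, percentiles, False)


def pc_vpc(
    model: PopulationModel,
    dataset: StudyDataset,
    n_replicates: int = 1000,
    bins=None,
    seed=None,
    percentiles: tuple = (5, 50, 95),
) -> VPCResult:
    """Prediction-corrected VPC.

    Observations and simulations are multiplied by
    (bin-median PRED) / (own PRED) before percentile computation; bins
    containing a non-positive PRED are excluded with a warning.
    """
    return _vpc_impl(model, dataset, n_replicates, bins, seed, percentiles, True)


def coverage(
    model: PopulationModel,
    dataset: StudyDataset,
    n_replicates: int = 1000,
    seed=None,
    band: tuple = (5, 95),
) -> dict:
    """Fraction of observations inside their own design point's simulated band.

    For every retained observation the model simulates ``n_replicates``
    values at that subject's exact design point; the returned fraction is the
    share of observations falling between the ``band`` percentiles of their
    own simulated distribution (~0.90 for a well-specified model with the
    default 5th–95th band). Also reports a per-visit breakdown.
    """
    rng = np.random.default_rng(seed)
    subjects = subjects_from_dataset(dataset)
    obs = _obs_frame(dataset)
    y = obs["DV"].to_numpy(dtype=float)
    sims = simulate_replicates(model, subjects, n_replicates, rng)
    lo = np.percentile(sims, band[0], axis=0)
    hi = np.percentile(sims, band[1], axis=0)
    inside = (y >= lo) & (y <= hi)
    visits = obs["VISIT"].astype(str).to_numpy()
    per_visit = {
        v: float(inside[visits == v].mean()) for v in pd.unique(visits)
    }
    return {
        "fraction": float(inside.mean()),
        "per_visit": per_visit,
        "n_observations": int(y.size),
        "n_replicates": n_replicates,
    }
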