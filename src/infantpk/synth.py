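"""Synthetic emulation of the infant propranolol PK study design.

The generator reproduces the trial structure: 22 infants in two age groups
(10 aged 35–90 days and 12 aged 91–150 days at inclusion), titration dosing
1 → 2 → 3 mg/kg/day BID with equal split, morning administrations around
08:00 and evening administrations around 17:00 except the evening before the
full PK day which is moved to 20:00 to give a regular 12-hour interval, and
the sparse sampling schedule (trough at D7 and D14; trough plus 1, 2, 4, 6
and 9 h post-dose on D28 for group 1 or D84 for group 2 — 8 samples per
infant). Weights follow group-specific lognormal distributions calibrated to
the observed visit medians, growing monotonically within subject; doses are
recomputed from the current weight. Concentrations are simulated from a
population model with lognormal between-subject effects and proportional
residual error, censored below the 0.5 ng/mL quantification limit, with
optional sampling-time jitter and gross-outlier injection to exercise the
cleaning rules.

Individual weights and ages of the real cohort are unpublished; the generator
matches summary statistics only.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from .dataset import StudyDataset
from .nlme import PopulationModel, SubjectData, individual_prediction

__all__ = [
    "StudyDesignConfig",
    "generate_population",
    "generate_dosing",
    "generate_observations",
    "generate_study",
]


@dataclass
class StudyDesignConfig:
    """Tunable description of the study design the generator emulates."""

    n_group1: int = 10
    n_group2: int = 12
    #: visit days and median weights (kg) per group; per-subject curves are
    #: these medians scaled by a lognormal subject factor. The group-2 curve
    #: is adjusted to be monotone (observed per-visit medians cross because
    #: visit-level n differs).
    weight_days_g1: tuple = (1, 7, 14, 28)
    weight_medians_g1: tuple = (4.8, 5.04, 5.25, 5.6)
    weight_days_g2: tuple = (1, 7, 14, 84)
    weight_medians_g2: tuple = (6.2, 6.25, 6.45, 7.65)
    weight_sd_log: float = 0.13
    age_range_g1: tuple = (50, 89)
    age_range_g2: tuple = (95, 151)
    #: mg/kg/day in titration weeks 1, 2, 3+
    titration: tuple = (1.0, 2.0, 3.0)
    morning_clock: float = 8.0
    evening_clock: float = 17.0
    pk_eve_clock: float = 20.0
    pk_day_g1: int = 28
    pk_day_g2: int = 84
    sample_offsets: tuple = (1.0, 2.0, 4.0, 6.0, 9.0)
    blq_limit: float = 0.5
    censor_blq: bool = True
    time_jitter_sd: float = 0.0
    n_outliers: int = 0
    outlier_factor: float = 7.0

    @classmethod
    def from_yaml(cls, path) -> "StudyDesignConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for name in (
            "weight_days_g1",
            "weight_medians_g1",
            "weight_days_g2",
            "weight_medians_g2",
            "age_range_g1",
            "age_range_g2",
            "titration",
            "sample_offsets",
        ):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_population(config: StudyDesignConfig, seed=None) -> pd.DataFrame:
    """Draw the virtual cohort: id, group, inclusion age, weight trajectory.

    Returns one row per subject with the visit-day weights (the subject's
    lognormal size factor applied to the group median curve, hence monotone
    within subject) and the PK-evaluation day.
    """
    rng = _as_rng(seed)
    rows = []
    sid = 0
    for grp, n, days, meds, ages, pk_day in (
        (1, config.n_group1, config.weight_days_g1, config.weight_medians_g1,
         config.age_range_g1, config.pk_day_g1),
        (2, config.n_group2, config.weight_days_g2, config.weight_medians_g2,
         config.age_range_g2, config.pk_day_g2),
    ):
        for _ in range(n):
            sid += 1
            z = rng.normal(0.0, config.weight_sd_log)
            age0 = float(rng.uniform(*ages))
            row = {
                "ID": sid,
                "GRP": grp,
                "AGE_D1": age0,
                "WFACTOR": float(np.exp(z)),
                "PK_DAY": pk_day,
            }
            for d, m in zip(days, meds):
                row[f"WT_D{d}"] = m * np.exp(z)
            rows.append(row)
    return pd.DataFrame(rows)


def _weight_at(config: StudyDesignConfig, subject: pd.Series, day: float) -> float:
    if subject["GRP"] == 1:
        days, meds = config.weight_days_g1, config.weight_medians_g1
    else:
        days, meds = config.weight_days_g2, config.weight_medians_g2
    return float(np.interp(day, days, meds) * subject["WFACTOR"])


def _daily_mg_per_kg(config: StudyDesignConfig, day: int) -> float:
    if day <= 7:
        return config.titration[0]
    if day <= 14:
        return config.titration[1]
    return config.titration[2]


def generate_dosing(
    subjects: pd.DataFrame, config: StudyDesignConfig
) -> dict[int, pd.DataFrame]:
    """BID dose events per subject up to the PK-day morning dose.

    Time 0 is the first morning administration (day 1, ~08:00). Evening doses
    fall ``evening_clock − morning_clock`` hours after the morning dose,
    except the evening before the PK day (moved to ``pk_eve_clock``). The
    per-administration amount is half the current daily mg/kg times the
    current weight.
    """
    evening_offset = config.evening_clock - config.morning_clock
    pk_eve_offset = config.pk_eve_clock - config.morning_clock
    out = {}
    for _, sub in subjects.iterrows():
        pk_day = int(sub["PK_DAY"])
        times, amounts, days = [], [], []
        for day in range(1, pk_day + 1):
            w = _weight_at(config, sub, day)
            amt = _daily_mg_per_kg(config, day) / 2.0 * w
            t0 = 24.0 * (day - 1)
            times.append(t0)
            amounts.append(amt)
            days.append(day)
            if day == pk_day:
                break  # sampling finishes before the PK-day afternoon dose
            off = pk_eve_offset if day == pk_day - 1 else evening_offset
            times.append(t0 + off)
            amounts.append(amt)
            days.append(day)
        out[int(sub["ID"])] = pd.DataFrame(
            {"TIME": times, "AMT": amounts, "DAY": days}
        )
    return out


def _sampling_schedule(config: StudyDesignConfig, pk_day: int) -> pd.DataFrame:
    """Nominal sampling times: visit label, study time (h), time after dose."""
    rows = [
        {"VISIT": "D7", "NTIME": 24.0 * 6, "TAD": 0.0, "DAY": 7},
        {"VISIT": "D14", "NTIME": 24.0 * 13, "TAD": 0.0, "DAY": 14},
    ]
    pk_label = f"D{pk_day}"
    t_pk = 24.0 * (pk_day - 1)
    rows.append({"VISIT": pk_label, "NTIME": t_pk, "TAD": 0.0, "DAY": pk_day})
    for off in config.sample_offsets:
        rows.append(
            {"VISIT": pk_label, "NTIME": t_pk + off, "TAD": off, "DAY": pk_day}
        )
    return pd.DataFrame(rows)


def generate_observations(
    subjects: pd.DataFrame,
    dosing: dict[int, pd.DataFrame],
    model: PopulationModel,
    config: StudyDesignConfig,
    seed=None,
) -> StudyDataset:
    """Simulate concentrations at the design's sampling times and assemble the dataset.

    Per subject, η ~ N(0, Ω) once; the concentration at each sample is the
    structural prediction (using that occasion's weight as covariate value)
    perturbed by proportional (and optional additive) residual error.
    Concentrations below the quantification limit become BLQ rows (flagged,
    no numeric DV). Deterministic given seed.
    """
    rng = _as_rng(seed)
    omega = model.omega_matrix()
    rows = []
    outlier_pool = []
    for _, sub in subjects.iterrows():
        sid = int(sub["ID"])
        doses = dosing[sid]
        sched = _sampling_schedule(config, int(sub["PK_DAY"]))
        times = sched["NTIME"].to_numpy(dtype=float).copy()
        if config.time_jitter_sd > 0:
            post = sched["TAD"].to_numpy() > 0
            times[post] = np.maximum(
                times[post] + rng.normal(0.0, config.time_jitter_sd, post.sum()),
                24.0 * (int(sub["PK_DAY"]) - 1) + 0.05,
            )
        wt = np.array([_weight_at(config, sub, d) for d in sched["DAY"]])
        sdata = SubjectData(
            id=sid,
            dose_times=doses["TIME"].to_numpy(),
            dose_amounts=doses["AMT"].to_numpy(),
            obs_times=times,
            y=np.zeros(len(times)),
            covariates={"wt": wt},
        )
        eta = (
            rng.multivariate_normal(np.zeros(model.n_eta), omega)
            if model.n_eta
            else np.empty(0)
        )
        f = individual_prediction(model, sdata, eta)
        eps1 = rng.normal(0.0, np.sqrt(model.sigma2_prop), f.size) if model.sigma2_prop else 0.0
        eps2 = rng.normal(0.0, np.sqrt(model.sigma2_add), f.size) if model.sigma2_add else 0.0
        y = f * (1.0 + eps1) + eps2

        for j in range(len(sched)):
            row = {
                "ID": sid,
                "TIME": times[j],
                "AMT": np.nan,
                "EVID": 0,
                "DV": y[j],
                "MDV": 0,
                "WT": wt[j],
                "AGE": sub["AGE_D1"] + sched["DAY"].iloc[j] - 1,
                "GRP": int(sub["GRP"]),
                "VISIT": sched["VISIT"].iloc[j],
                "BLQ": 0,
                "TAD": sched["TAD"].iloc[j],
                "NTIME": sched["NTIME"].iloc[j],
            }
            if config.censor_blq and y[j] < config.blq_limit:
                row["DV"] = np.nan
                row["MDV"] = 1
                row["BLQ"] = 1
            elif sched["TAD"].iloc[j] > 0:
                outlier_pool.append(len(rows))
            rows.append(row)

        for _, d in doses.iterrows():
            rows.append(
                {
                    "ID": sid,
                    "TIME": d["TIME"],
                    "AMT": d["AMT"],
                    "EVID": 1,
                    "DV": np.nan,
                    "MDV": 1,
                    "WT": _weight_at(config, sub, d["DAY"]),
                    "AGE": sub["AGE_D1"] + d["DAY"] - 1,
                    "GRP": int(sub["GRP"]),
                    "VISIT": f"D{int(d['DAY'])}",
                    "BLQ": 0,
                    "TAD": 0.0,
                    "NTIME": d["TIME"],
                }
            )

    df = pd.DataFrame(rows)
    if config.n_outliers > 0 and outlier_pool:
        picks = rng.choice(
            np.array(outlier_pool), size=min(config.n_outliers, len(outlier_pool)),
            replace=False,
        )
        df.loc[picks, "DV"] *= config.outlier_factor
    # observations precede doses at identical times (trough drawn pre-dose)
    df = df.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)
    return StudyDataset(df)


def generate_study(
    model: PopulationModel, config: StudyDesignConfig | None = None, seed=None
) -> StudyDataset:
    """Convenience wrapper: population → dosing → observations with one seed."""
    config = config or StudyDesignConfig()
    rng = _as_rng(seed)
    subjects = generate_population(config, rng)
    dosing = generate_dosing(subjects, config)
    return generate_observations(subjects, dosing, model, config, rng)
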