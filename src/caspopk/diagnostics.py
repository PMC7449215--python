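"""Model diagnostics: goodness of fit, pcVPC, external validation.

Prediction error is defined as ``observed - predicted``; bias is the mean
weighted prediction error and imprecision the bias-adjusted mean weighted
squared prediction error, both weighted by the reciprocal variance of the
observation (``1 / SD^2`` from the assay-error model).

The visual predictive check is prediction-corrected: every observed and
simulated concentration is rescaled by (bin-median population prediction) /
(its own population prediction) before percentiles are taken, which removes
the spread contributed by dose and weight differences between subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pk_core import Covariates, Regimen, _conc_grid
from .popfit import (
    ErrorModel,
    NPDistribution,
    ObservationRecord,
    Subject,
    observation_sd,
    _predict_matrix,
)

__all__ = [
    "GofReport",
    "VpcResult",
    "gof_metrics",
    "pcvpc",
    "external_validate",
    "read_external_dataset",
    "population_predictions",
]

#: Nominal sampling offsets after an infusion start (h); pcVPC default bins
#: are these +/- 0.5 h on the time-since-last-dose axis.
NOMINAL_OFFSETS = (0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)


@dataclass(frozen=True)
class GofReport:
    observed: np.ndarray
    predicted: np.ndarray
    r: float
    bias: float
    imprecision: float
    n: int


@dataclass(frozen=True)
class VpcResult:
    """Per-bin 5th/50th/95th percentile curves, observed and simulated.

    `sim_percentiles` is the median across replicates of the per-replicate
    percentile; `band_lo`/`band_hi` bracket the replicate percentiles at
    2.5/97.5% and serve as the simulated confidence band for each curve.
    """

    bin_centers: np.ndarray
    obs_percentiles: np.ndarray  # (3, n_bins) rows: 5th, 50th, 95th
    sim_percentiles: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray
    n_sim: int
    n_excluded: int = 0


def gof_metrics(
    observed: Sequence[float], predicted: Sequence[float], em: ErrorModel
) -> GofReport:
    """Pearson r plus weighted bias and imprecision of predictions."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("need >= 2 equal-length (observed, predicted) pairs")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise ValueError("zero variance in observed or predicted values")
    w = 1.0 / np.asarray(observation_sd(em, obs)) ** 2
    err = obs - pred
    bias = float((w * err).sum() / w.sum())
    imprecision = float((w * err * err).sum() / w.sum() - bias * bias)
    r = float(np.corrcoef(obs, pred)[0, 1])
    return GofReport(
        observed=obs, predicted=pred, r=r, bias=bias,
        imprecision=max(imprecision, 0.0), n=obs.size,
    )


def population_predictions(subject: Subject, dist: NPDistribution) -> np.ndarray:
    """Prior-weighted mean model prediction at the subject's sampling times."""
    preds = _predict_matrix(subject, dist.support)
    return dist.weights @ preds


def _time_after_dose(subject: Subject, t: float) -> float:
    starts = [e.start for e in subject.regimen.events if e.start < t]
    return t - max(starts) if starts else t


def _default_bins() -> list[tuple[float, float, float]]:
    return [(c - 0.5, c + 0.5, c) for c in NOMINAL_OFFSETS]


def pcvpc(
    subjects: Sequence[Subject],
    dist: NPDistribution,
    em: ErrorModel,
    bins: Sequence[tuple[float, float]] | None = None,
    n_sim: int = 500,
    seed: int = 20200820,
) -> VpcResult:
    """Prediction-corrected visual predictive check.

    Simulates `n_sim` replicates of the observed design (parameters sampled
    from the fitted distribution by mass, residual noise from the error
    model), prediction-corrects observed and simulated values alike, and
    returns 5/50/95 percentile curves per time-after-dose bin.
    """
    if not subjects:
        raise ValueError("at least one subject is required")
    if bins is None:
        bin_defs = _default_bins()
    else:
        bin_defs = [(lo, hi, 0.5 * (lo + hi)) for lo, hi in bins]
    if not bin_defs:
        raise ValueError("at least one bin is required")
    rng = np.random.default_rng(seed)

    # flatten the design: (subject index, time, observed, population pred, tad)
    recs = []
    for si, s in enumerate(subjects):
        pop = population_predictions(s, dist)
        for o, pp in zip(s.observations, pop):
            recs.append((si, o.time, o.concentration, pp, _time_after_dose(s, o.time)))
    df = pd.DataFrame(recs, columns=["subject", "time", "obs", "pop", "tad"])
    n_excluded = int((df["pop"] <= 0).sum())
    df = df[df["pop"] > 0].reset_index(drop=True)

    df["bin"] = -1
    for b, (lo, hi, _) in enumerate(bin_defs):
        df.loc[(df["tad"] >= lo) & (df["tad"] <= hi), "bin"] = b
    df = df[df["bin"] >= 0].reset_index(drop=True)
    if df.empty:
        raise ValueError("no observations fall inside the requested bins")
    bin_median_pop = df.groupby("bin")["pop"].median()
    df["corr"] = df["bin"].map(bin_median_pop) / df["pop"]
    df["pc_obs"] = df["obs"] * df["corr"]

    used_bins = sorted(df["bin"].unique())
    qs = (5.0, 50.0, 95.0)
    obs_p = np.stack(
        [
            np.percentile(df.loc[df["bin"] == b, "pc_obs"], qs)
            for b in used_bins
        ],
        axis=1,
    )

    # simulate replicates at the observed design
    support, mass = dist.support, dist.weights
    pred_cache = [_predict_matrix(s, support) for s in subjects]
    sim_p = np.empty((n_sim, 3, len(used_bins)))
    sim_vals = np.empty(len(df))
    rows_by_subject = {si: np.flatnonzero(df["subject"].to_numpy() == si)
                       for si in df["subject"].unique()}
    obs_index_within = {}
    for si in rows_by_subject:
        s = subjects[si]
        times = [o.time for o in s.observations]
        kept_times = df.loc[rows_by_subject[si], "time"].to_numpy()
        obs_index_within[si] = np.array([times.index(t) for t in kept_times])
    corr = df["corr"].to_numpy()
    bins_arr = df["bin"].to_numpy()
    for r_i in range(n_sim):
        for si, rows in rows_by_subject.items():
            j = rng.choice(len(mass), p=mass)
            pred = pred_cache[si][j][obs_index_within[si]]
            sd = np.asarray(observation_sd(em, pred))
            sim_vals[rows] = np.maximum(pred + rng.normal(0.0, 1.0, pred.size) * sd, 0.0)
        pc_sim = sim_vals * corr
        for k, b in enumerate(used_bins):
            sim_p[r_i, :, k] = np.percentile(pc_sim[bins_arr == b], qs)

    return VpcResult(
        bin_centers=np.array([bin_defs[b][2] for b in used_bins]),
        obs_percentiles=obs_p,
        sim_percentiles=np.median(sim_p, axis=0),
        band_lo=np.percentile(sim_p, 2.5, axis=0),
        band_hi=np.percentile(sim_p, 97.5, axis=0),
        n_sim=n_sim,
        n_excluded=n_excluded,
    )


def read_external_dataset(path, seed: int = 20200820) -> list[Subject]:
    """Read an external-validation CSV (popfit dialect + optional wt_min/wt_max).

    Digitized cohorts often report only a weight range; rows lacking a
    weight but carrying ``wt_min``/``wt_max`` get a uniform draw from that
    range (one draw per subject, governed by `seed`).
    """
    df = pd.read_csv(path)
    rng = np.random.default_rng(seed)
    if "weight" not in df.columns:
        df["weight"] = np.nan
    if {"wt_min", "wt_max"}.issubset(df.columns):
        for sid, grp in df.groupby("id", sort=False):
            if grp["weight"].isna().all():
                lo, hi = grp["wt_min"].iloc[0], grp["wt_max"].iloc[0]
                if not (pd.isna(lo) or pd.isna(hi)):
                    df.loc[grp.index, "weight"] = rng.uniform(lo, hi)
        df = df.drop(columns=["wt_min", "wt_max"])
    import io as _io

    from .popfit import read_dataset

    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return read_dataset(buf)


def external_validate(
    dist: NPDistribution,
    em: ErrorModel,
    external: Sequence[Subject],
) -> GofReport:
    """Population-level fit of an independent cohort without refitting.

    Pure evaluation: predicts the external design from the fitted
    distribution's prior-weighted mean and pools all (observed, predicted)
    pairs into one goodness-of-fit report.
    """
    if not external:
        raise ValueError("external validation set is empty")
    obs_all, pred_all = [], []
    for s in external:
        if not s.regimen.events:
            raise ValueError(f"external subject {s.id} has no dosing history")
        obs_all.append(s.concentrations)
        pred_all.append(population_predictions(s, dist))
    return gof_metrics(np.concatenate(obs_all), np.concatenate(pred_all), em)
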