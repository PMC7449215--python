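"""Study-like synthetic cohorts with known ground truth.

Emulates the ICU cohort design: 20 adult critically ill patients on label
(SmPC) caspofungin dosing, rich sampling on day 3 of therapy (pre-dose and
1, 2, 3, 4, 6, 8, 12, 24 h after the infusion start), five patients with a
second sampling occasion three days later after a dose escalation, six
samples missing on six distinct occasions, for 219 concentrations in
total.  Body weights honour the cohort anchors exactly (min 48, median 78,
max 139 kg).  True parameters per subject are drawn from a configurable
generating distribution; concentrations are model predictions plus
Gaussian noise with the assay-error SD.

Everything is reproducible from a single seed, and a cohort written to CSV
round-trips through the dataset reader unchanged.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .pk_core import Covariates, DoseEvent, PKParameters, Regimen
from .popfit import ErrorModel, ObservationRecord, Subject, observation_sd, write_dataset

__all__ = [
    "TRUTH_MOMENTS",
    "TRUTH_MEDIANS",
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "smpc_regimen",
    "write_cohort",
]

#: Population (mean, SD) used by the default log-normal generating truth.
TRUTH_MOMENTS: dict[str, tuple[float, float]] = {
    "ke": (0.09, 0.04),
    "v0": (7.71, 2.70),
    "kcp": (0.44, 0.38),
    "kpc": (0.46, 0.35),
}

#: Population medians, used by the point and two-point generating truths.
TRUTH_MEDIANS: dict[str, float] = {"ke": 0.08, "v0": 7.20, "kcp": 0.28, "kpc": 0.34}

#: Sampling offsets (h) after an occasion's infusion start; 0 is pre-dose.
SAMPLE_OFFSETS = (0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)

# Table-1-style covariate ranges used purely as screen fodder (min, max,
# log-uniform flag for skewed labs); no physiological coupling is claimed.
_COVARIATE_RANGES = {
    "age": (25.0, 83.0, False),
    "albumin": (14.0, 28.0, False),
    "crp": (56.0, 287.0, False),
    "saps3": (31.0, 104.0, False),
    "bilirubin": (3.0, 376.0, True),
    "asat": (12.0, 1776.0, True),
    "alat": (7.0, 598.0, True),
    "ggt": (16.0, 941.0, True),
}


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic study cohort.

    `truth` selects the generating distribution: ``lognormal`` (independent
    log-normals at the published population moments), ``point`` (everyone at
    the population medians) or ``two-point`` (Ke 0.04 vs 0.16 split 50/50,
    other parameters at the medians).  `noise_sd_scale` multiplies the
    assay-error SD; 0 yields noise-free observations.
    """

    n_subjects: int = 20
    weight_min: float = 48.0
    weight_median: float = 78.0
    weight_max: float = 139.0
    n_repeat_occasions: int = 5
    n_dropped_samples: int = 6
    truth: str = "lognormal"
    error: ErrorModel = field(default_factory=lambda: ErrorModel(scale=0.654))
    noise_sd_scale: float = 1.0
    repeat_escalation: float = 1.4
    seed: int = 20200820

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("need >= 3 subjects to honour min/median/max anchors")
        if not (self.weight_min < self.weight_median < self.weight_max):
            raise ValueError("weight anchors must be ordered min < median < max")
        if self.n_repeat_occasions > self.n_subjects:
            raise ValueError("cannot repeat more occasions than subjects")
        n_occ = self.n_subjects + self.n_repeat_occasions
        if self.n_dropped_samples > n_occ:
            raise ValueError("at most one dropped sample per occasion")
        if self.truth not in ("lognormal", "point", "two-point"):
            raise ValueError(f"unknown truth kind {self.truth!r}")


@dataclass(frozen=True)
class SyntheticCohort:
    subjects: tuple[Subject, ...]
    truth: dict[str, PKParameters]
    manifest: dict

    @property
    def n_concentrations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)


def smpc_regimen(
    weight: float,
    hepatic: str | None = None,
    days: int = 3,
    escalate_from_day: int | None = None,
    escalation: float = 1.0,
) -> Regimen:
    """Label dosing: 70 mg load, then 50 mg daily (<=80 kg) or 70 mg
    (>80 kg); 35 and 50 mg respectively under moderate hepatic impairment
    (Child-Pugh B, score 7-9).  1-h infusions every 24 h.

    `escalate_from_day` (1-based) multiplies maintenance doses from that
    day on by `escalation` (dose adjustment after a low-exposure occasion).
    """
    if weight <= 0:
        raise ValueError("weight must be > 0")
    if days < 1:
        raise ValueError("days must be >= 1")
    if hepatic is not None and hepatic.upper() == "B":
        maintenance = 35.0 if weight <= 80.0 else 50.0
    else:
        maintenance = 50.0 if weight <= 80.0 else 70.0
    events = []
    for day in range(days):
        amount = 70.0 if day == 0 else maintenance
        if (
            escalate_from_day is not None
            and day + 1 >= escalate_from_day
            and day > 0
        ):
            amount = maintenance * escalation
        events.append(DoseEvent(amount=amount, start=day * 24.0, duration=1.0))
    return Regimen(events, horizon=days * 24.0)


def _cohort_weights(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Weights honouring min/median/max exactly, remainder rank-adjusted.

    One subject is pinned to each extreme anchor; the median anchor is
    occupied by one subject (odd n) or two (even n), and the remaining
    subjects split evenly below and above so the sample median equals the
    anchor exactly.
    """
    n = spec.n_subjects
    n_median = 2 if n % 2 == 0 else 1
    n_free = n - 2 - n_median
    n_below = n_free // 2
    n_above = n_free - n_below
    below = rng.uniform(spec.weight_min, spec.weight_median, n_below)
    above = rng.uniform(spec.weight_median, spec.weight_max, n_above)
    weights = np.concatenate(
        [
            [spec.weight_min],
            below,
            np.full(n_median, spec.weight_median),
            above,
            [spec.weight_max],
        ]
    )
    return np.round(weights[rng.permutation(n)], 1)


def _draw_truth(spec: CohortSpec, rng: np.random.Generator) -> list[PKParameters]:
    n = spec.n_subjects
    if spec.truth == "point":
        return [PKParameters(**TRUTH_MEDIANS)] * n
    if spec.truth == "two-point":
        kes = np.where(rng.permutation(n) % 2 == 0, 0.04, 0.16)
        med = dict(TRUTH_MEDIANS)
        return [
            PKParameters(ke=float(k), v0=med["v0"], kcp=med["kcp"], kpc=med["kpc"])
            for k in kes
        ]
    params = []
    for _ in range(n):
        values = {}
        for name, (mean, sd) in TRUTH_MOMENTS.items():
            mu = math.log(mean * mean / math.sqrt(mean * mean + sd * sd))
            sigma = math.sqrt(math.log(1.0 + (sd / mean) ** 2))
            values[name] = float(np.exp(rng.normal(mu, sigma)))
        params.append(PKParameters(**values))
    return params


def _sample_covariates(rng: np.random.Generator) -> dict[str, float]:
    extra = {}
    for name, (lo, hi, log_uniform) in _COVARIATE_RANGES.items():
        if log_uniform:
            extra[name] = float(
                np.round(np.exp(rng.uniform(np.log(lo), np.log(hi))), 1)
            )
        else:
            extra[name] = float(np.round(rng.uniform(lo, hi), 1))
    extra["sex"] = float(rng.integers(0, 2))
    extra["dialysis"] = float(rng.random() < 0.4)
    extra["steroids"] = float(rng.random() < 0.55)
    return extra


def generate_cohort(spec: CohortSpec | None = None) -> SyntheticCohort:
    """Generate a study-like cohort with known per-subject parameters.

    Occasion 1 samples on day 3 (dose at 48 h; pre-dose trough at 48 h,
    then the nominal offsets).  Repeat-occasion subjects continue dosing
    with maintenance escalated by `repeat_escalation` from day 4 and are
    resampled on day 6.  Dropped samples (default 6) are removed from
    distinct occasions, never the pre-dose one.
    """
    spec = CohortSpec() if spec is None else spec
    rng = np.random.default_rng(spec.seed)
    weights = _cohort_weights(spec, rng)
    truths = _draw_truth(spec, rng)
    repeat_ids = set(
        rng.choice(spec.n_subjects, size=spec.n_repeat_occasions, replace=False)
    )

    # occasions: (subject index, occasion number, dose start h)
    occasions: list[tuple[int, int, float]] = []
    for i in range(spec.n_subjects):
        occasions.append((i, 1, 48.0))
        if i in repeat_ids:
            occasions.append((i, 2, 120.0))
    drop_occ = rng.choice(len(occasions), size=spec.n_dropped_samples, replace=False)
    dropped_offsets = {
        int(k): float(rng.choice(SAMPLE_OFFSETS[1:])) for k in drop_occ
    }

    subjects = []
    truth_table: dict[str, PKParameters] = {}
    for i in range(spec.n_subjects):
        sid = f"S{i + 1:02d}"
        wkg = float(weights[i])
        days = 6 if i in repeat_ids else 3
        regimen = smpc_regimen(
            wkg,
            days=days,
            escalate_from_day=4 if i in repeat_ids else None,
            escalation=spec.repeat_escalation,
        )
        params = truths[i]
        cov = Covariates(weight=wkg, extra=_sample_covariates(rng))
        obs: list[ObservationRecord] = []
        for k, (subj_idx, occ, start) in enumerate(occasions):
            if subj_idx != i:
                continue
            offsets = [
                off for off in SAMPLE_OFFSETS
                if dropped_offsets.get(k) != off
            ]
            times = np.array([start + off for off in offsets])
            pred = _predict(params, cov, regimen, times)
            sd = spec.noise_sd_scale * np.asarray(
                observation_sd(spec.error, pred)
            )
            conc = np.maximum(pred + rng.normal(0.0, 1.0, pred.size) * sd, 0.0)
            obs.extend(
                ObservationRecord(float(t), float(c), occasion=occ)
                for t, c in zip(times, conc)
            )
        subjects.append(Subject(id=sid, regimen=regimen, observations=obs, covariates=cov))
        truth_table[sid] = params

    manifest = {
        "seed": spec.seed,
        "n_subjects": spec.n_subjects,
        "n_occasions": len(occasions),
        "n_concentrations": sum(len(s.observations) for s in subjects),
        "n_dropped": spec.n_dropped_samples,
        "truth": spec.truth,
        "weights": {"min": float(weights.min()),
                    "median": float(np.median(weights)),
                    "max": float(weights.max())},
    }
    return SyntheticCohort(tuple(subjects), truth_table, manifest)


def _predict(params, cov, regimen, times):
    from .pk_core import concentration_profile

    return concentration_profile(params, cov, regimen, times).concentrations


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    """Write cohort CSV, truth table CSV and JSON manifest; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dataset": outdir / "cohort.csv",
        "truth": outdir / "truth.csv",
        "manifest": outdir / "manifest.json",
    }
    write_dataset(cohort.subjects, paths["dataset"])
    with open(paths["truth"], "w") as fh:
        fh.write("id,ke,v0,kcp,kpc\n")
        for sid, p in cohort.truth.items():
            fh.write(f"{sid},{p.ke:.10g},{p.v0:.10g},{p.kcp:.10g},{p.kpc:.10g}\n")
    with open(paths["manifest"], "w") as fh:
        json.dump(cohort.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
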