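"""Diagnostics for the fitted population model.

Computes population and individual goodness of fit (Pearson r, weighted
bias, bias-adjusted weighted imprecision), the prediction-corrected visual
predictive check, and a self-style external validation: a fresh cohort
generated from the fitted distribution itself, predicted without refitting.

Reads results/cohort + results/fit; writes results/diagnostics/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from caspopk.diagnostics import external_validate, gof_metrics, pcvpc, population_predictions
from caspopk.popfit import (
    ErrorModel,
    bayes_posterior,
    load_distribution,
    read_dataset,
    _predict_matrix,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "diagnostics"


def main() -> None:
    subjects = read_dataset(ROOT / "cohort" / "cohort.csv")
    dist = load_distribution(ROOT / "fit" / "distribution.json")
    meta = json.loads((ROOT / "fit" / "distribution.json").read_text())
    err = meta["error"]
    em = ErrorModel(c0=err["c0"], c1=err["c1"], mode=err["mode"], scale=err["scale"])
    OUT.mkdir(parents=True, exist_ok=True)

    obs, pop_pred, ind_pred = [], [], []
    for s in subjects:
        obs.append(s.concentrations)
        pop_pred.append(population_predictions(s, dist))
        _, pm = bayes_posterior(s, dist, em)
        ind_pred.append(_predict_matrix(s, pm.as_array()[None, :])[0])
    obs, pop_pred, ind_pred = map(np.concatenate, (obs, pop_pred, ind_pred))
    pop = gof_metrics(obs, pop_pred, em)
    ind = gof_metrics(obs, ind_pred, em)
    gof = pd.DataFrame(
        dict(level=["population", "individual"], r=[pop.r, ind.r],
             bias=[pop.bias, ind.bias],
             imprecision=[pop.imprecision, ind.imprecision], n=[pop.n, ind.n])
    )
    gof.to_csv(OUT / "gof.csv", index=False)
    print("goodness of fit (observed vs predicted, pooled):")
    print(gof.round(4).to_string(index=False))

    vpc = pcvpc(subjects, dist, em, n_sim=500, seed=20200820)
    pd.DataFrame(
        dict(bin_center=vpc.bin_centers,
             obs_p5=vpc.obs_percentiles[0], obs_p50=vpc.obs_percentiles[1],
             obs_p95=vpc.obs_percentiles[2],
             sim_p5=vpc.sim_percentiles[0], sim_p50=vpc.sim_percentiles[1],
             sim_p95=vpc.sim_percentiles[2])
    ).to_csv(OUT / "pcvpc.csv", index=False)
    inside = (
        (vpc.obs_percentiles >= vpc.band_lo) & (vpc.obs_percentiles <= vpc.band_hi)
    ).mean()
    print(f"pcVPC: observed percentile curves inside simulated bands in "
          f"{100*inside:.0f}% of bin/curve cells ({vpc.n_sim} replicates)")

    # external validation against a cohort regenerated from the fitted model
    from caspopk.synthetic import CohortSpec, generate_cohort

    ext = generate_cohort(CohortSpec(seed=4242, truth="lognormal")).subjects
    rep = external_validate(dist, em, list(ext))
    with open(OUT / "external_validation.json", "w") as fh:
        json.dump(dict(r=rep.r, bias=rep.bias, imprecision=rep.imprecision,
                       n=rep.n), fh, indent=2)
        fh.write("\n")
    print(f"external validation (independent synthetic cohort): "
          f"r = {rep.r:.3f}, bias = {rep.bias:.3f} mg/L, n = {rep.n}")


if __name__ == "__main__":
    main()
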