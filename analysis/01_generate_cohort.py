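"""Generate the synthetic study cohort.

Emulates the ICU study design: 20 critically ill adults on label
caspofungin dosing (70 mg load; 50 mg daily <=80 kg, 70 mg >80 kg; 1-h
infusions), nine samples per dosing occasion on day 3, five subjects
resampled three days later after a dose escalation, six samples lost on
distinct occasions.  True parameters come from independent log-normals at
the published population moments.

Writes results/cohort/{cohort.csv, truth.csv, manifest.json}.
"""

from pathlib import Path

from caspopk.synthetic import CohortSpec, generate_cohort, write_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    cohort = generate_cohort(CohortSpec())
    paths = write_cohort(cohort, OUT)
    m = cohort.manifest
    print(
        f"cohort: {m['n_subjects']} subjects, {m['n_occasions']} occasions, "
        f"{m['n_concentrations']} concentrations"
    )
    print(
        f"weights: min {m['weights']['min']:.0f}, median {m['weights']['median']:.0f}, "
        f"max {m['weights']['max']:.0f} kg"
    )
    print(f"wrote {paths['dataset']}")


if __name__ == "__main__":
    main()
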