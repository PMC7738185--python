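"""Simulate a two-group (CTL vs TIC) cohort and write every modality fixture.

Generates a control truth and a diseased truth carrying the planted effects
(thickness x1.4, leaflet area x1.3, D1 fiber concentration x1.5), draws 10
subjects per group with 10% between-subject variability, and writes the
per-subject contour CSVs, a biaxial record, an IHC raster, an intensity
matrix, and the ground-truth sidecar under results/simulated/.
"""

from pathlib import Path

import numpy as np

from valvescale import io, synthetic

OUT = Path("results/simulated")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth_ctl = synthetic.default_truth(seed=SEED)
    truth_tic = truth_ctl.scaled(thickness=1.4, area=1.3, kappa_d1=1.5)
    truth_tic.de_log2fc = {f"P{i:04d}": 2.0 * (1 if i % 2 else -1) for i in range(10)}

    cohort = synthetic.gen_cohort(
        truth_ctl, truth_tic, n_ctl=10, n_tic=10, include_biax=False,
        include_omics=True, seed=SEED,
    )
    for sub in cohort.subjects:
        io.write_contours_csv(sub.section, OUT / f"{sub.subject_id}_section.csv")
    io.write_intensity_tsv(
        cohort.intensity_matrix, OUT / "intensities.tsv", OUT / "groups.tsv"
    )
    rec = synthetic.gen_biax_record(truth_ctl, noise_sd_mm=0.005, force_noise_sd_mN=1.0)
    io.write_biax_csv(rec, OUT / "biax_ctl_example.csv")
    image, section, attained = synthetic.gen_ihc_image(truth_ctl)
    io.write_image_tiff(image.positive, OUT / "ihc_positive.tif")
    io.write_contours_csv(section, OUT / "ihc_contours.csv")
    io.write_json(
        {
            "seed": SEED,
            "n_ctl": 10,
            "n_tic": 10,
            "planted_effects": {"thickness": 1.4, "area": 1.3, "kappa_d1": 1.5},
            "planted_de_log2fc": truth_tic.de_log2fc,
            "ihc_attained_fractions": attained,
        },
        OUT / "ground_truth.json",
    )
    print(f"wrote {len(cohort.subjects)} subjects and shared fixtures to {OUT}")


if __name__ == "__main__":
    main()
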