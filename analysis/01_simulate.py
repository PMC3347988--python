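"""Generate the synthetic study data with known planted truth.

Writes two datasets under results/data/: a noise-free one, in which every
downstream stage must be exact, and a noisy one at the experimental design
(3 biological replicates, 0.25 log2 biological SD) used for the operating
characteristics.  Also writes the 13-fraction gradient profile and the
triplicate q-PCR plate.
"""

from pathlib import Path

from polyshift import io as pio
from polyshift.config import SimConfig
from polyshift.simulate import (
    generate_ct_table,
    generate_expression_dataset,
    generate_fraction_profiles,
)

OUT = Path("results/data")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    noise_free = SimConfig(
        sigma_bio=0.0, sigma_tech=0.0,
        sample_scale_range=(1.0, 1.0), sample_offset_range=(0.0, 0.0),
        seed=SEED,
    )
    noisy = SimConfig(seed=SEED)

    for tag, cfg in (("noise_free", noise_free), ("noisy", noisy)):
        matrix, design, truth = generate_expression_dataset(cfg)
        pio.write_expression_matrix(matrix, OUT / f"matrix_{tag}.tsv")
        pio.write_design(design, OUT / f"design_{tag}.tsv")
        pio.write_truth(truth, OUT / f"truth_{tag}.tsv")
        counts = truth.true_class.value_counts().to_dict()
        print(f"{tag}: {len(design)} samples, {len(truth)} genes, classes {counts}")

    profiles = generate_fraction_profiles(noisy)
    pio.write_profiles(profiles, OUT / "profiles.tsv")
    print(f"gradient: {len(profiles)} fractions, "
          f"sucrose {profiles[0].sucrose_pct:.1f}-{profiles[-1].sucrose_pct:.1f}%")

    _, _, truth = generate_expression_dataset(noisy)
    ct = generate_ct_table(truth, noisy)
    pio.write_ct_table(ct, OUT / "ct_plate.csv")
    n_norm = ct.loc[ct.is_normalizer, "gene_id"].nunique()
    print(f"q-PCR plate: {ct.gene_id.nunique()} genes "
          f"({n_norm} normalizers), {len(ct)} wells")


if __name__ == "__main__":
    main()
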