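"""Classify genes into Up / Down / Equal and score against planted truth.

Applies the screen (fdr < 0.05, |M| > 1), the |M| > 2 call threshold and
the directional filters that exclude total-mRNA artifacts, then the TOST
equivalence call, and writes the heatmap-ordered display matrix plus the
confusion table against the simulator's truth.
"""

from pathlib import Path

import pandas as pd

from polyshift.classify import classify_genes, order_for_heatmap
from polyshift.config import Thresholds

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    th = Thresholds()
    for tag in ("noise_free", "noisy"):
        res = pd.read_csv(OUT / f"shift_results_{tag}.tsv", sep="\t",
                          index_col="gene_id")
        truth = pd.read_csv(DATA / f"truth_{tag}.tsv", sep="\t")
        labelled, summary = classify_genes(res, th)
        labelled.to_csv(OUT / f"classified_{tag}.tsv", sep="\t")
        order_for_heatmap(labelled).to_csv(OUT / f"heatmap_{tag}.tsv", sep="\t")

        merged = labelled.join(truth.set_index("gene_id"))
        confusion = pd.crosstab(merged.true_class, merged.gene_class)
        confusion.to_csv(OUT / f"confusion_{tag}.tsv", sep="\t")

        up_true = merged.true_class == "up"
        called_up = merged.gene_class == "up"
        sens = (up_true & called_up).sum() / up_true.sum()
        fdp = (called_up & ~up_true).sum() / max(called_up.sum(), 1)
        artifacts = merged[merged.true_class == "mrna_artifact"]
        leaked = artifacts.gene_class.isin(["up", "down"]).sum()
        print(f"{tag}: screen {summary['screen_up']}/{summary['screen_down']} "
              f"(up/down), Up = {summary['up']}, Down = {summary['down']}, "
              f"Equal = {summary['equal']}")
        print(f"  up sensitivity {sens:.3f}, up FDP {fdp:.3f}, "
              f"artifact genes leaked into Up/Down: {leaked}")


if __name__ == "__main__":
    main()
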