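"""Threshold-and-filter classification of genes into Up / Down / Equal.

The cascade screens on significance and effect size (fdr < 0.05 and
|M| > 1), then applies strict directional conditions on the four group
means so that apparent shifts caused by changes in total mRNA steady-state
levels (which move both fractions) are excluded:

    Up:    M >  m_call, p6 > p0, p6 > np6, np6 < np0, p0 < np0
    Down:  M < -m_call, p6 < p0, p0 > np0

Genes not called Up or Down are declared Equal when the TOST equivalence
p-value falls below alpha; everything else is Unclassified.  All
inequalities are strict; exact ties fail the condition.
"""

from __future__ import annotations

import pandas as pd

from .config import Thresholds

REQUIRED = ("p0", "p6", "np0", "np6", "M", "fdr", "p_tost")
CLASS_ORDER = ("up", "down", "equal", "unclassified")


def classify_genes(
    results: pd.DataFrame, thresholds: Thresholds | None = None
) -> tuple[pd.DataFrame, dict]:
    """Label every gene and summarize the class sizes.

    Parameters
    ----------
    results : DataFrame
        Indexed by gene_id with columns p0, p6, np0, np6, M, fdr, p_tost.
    thresholds : Thresholds
        Screen and call cut-offs; defaults per the standard cascade.

    Returns
    -------
    labelled : DataFrame
        ``results`` with an added ``gene_class`` column in
        {up, down, equal, unclassified}.
    summary : dict
        Sizes of the fdr/|M| screen (split by sign) and of the three
        final classes.
    """
    th = thresholds or Thresholds()
    for col in REQUIRED:
        if col not in results.columns:
            raise ValueError(f"results table lacks required column '{col}'")
        bad = results.index[results[col].isna()]
        if len(bad):
            raise ValueError(f"gene {bad[0]!r}: missing value in field '{col}'")

    r = results
    screen = (r["fdr"] < th.fdr_max) & (r["M"].abs() > th.m_screen)
    up = (
        screen
        & (r["M"] > th.m_call)
        & (r["p6"] > r["p0"])
        & (r["p6"] > r["np6"])
        & (r["np6"] < r["np0"])
        & (r["p0"] < r["np0"])
    )
    down = (
        screen
        & (r["M"] < -th.m_call)
        & (r["p6"] < r["p0"])
        & (r["p0"] > r["np0"])
    )
    equal = ~up & ~down & (r["p_tost"] < th.alpha_eq)

    labelled = r.copy()
    labelled["gene_class"] = "unclassified"
    labelled.loc[equal, "gene_class"] = "equal"
    labelled.loc[down, "gene_class"] = "down"
    labelled.loc[up, "gene_class"] = "up"

    summary = {
        "screen_up": int((screen & (r["M"] > 0)).sum()),
        "screen_down": int((screen & (r["M"] < 0)).sum()),
        "up": int(up.sum()),
        "down": int(down.sum()),
        "equal": int(equal.sum()),
        "unclassified": int((labelled["gene_class"] == "unclassified").sum()),
    }
    return labelled, summary


def order_for_heatmap(labelled: pd.DataFrame) -> pd.DataFrame:
    """Display matrix for the classified genes, heatmap-ready.

    Genes are grouped into Up, Down, Equal blocks (empty blocks omitted),
    each sorted by descending M, and the five display columns
    (p0, np0, p6, np6, M) are emitted along with the class label.
    Unclassified genes are not displayed.
    """
    blocks = []
    for cls in ("up", "down", "equal"):
        block = labelled[labelled["gene_class"] == cls]
        if len(block):
            blocks.append(block.sort_values("M", ascending=False))
    if not blocks:
        return pd.DataFrame(columns=["p0", "np0", "p6", "np6", "M", "gene_class"])
    ordered = pd.concat(blocks)
    return ordered[["p0", "np0", "p6", "np6", "M", "gene_class"]]
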