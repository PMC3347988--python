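"""Check gradient linearity and derive the fraction pooling plan.

Reads the simulated 13-fraction profile, verifies the sucrose gradient is
linear in fraction index, classifies fractions by their 28S/18S rRNA ratio
(close to 2 = assembled ribosomes = polysomal) and writes the pooling plan.
"""

import json
from pathlib import Path

from polyshift import io as pio
from polyshift.fractions import check_gradient_linearity, classify_fractions

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    profiles = pio.read_profiles(DATA / "profiles.tsv")

    lin = check_gradient_linearity(profiles, r2_min=0.98, resid_max=2.0)
    print(f"gradient fit: {lin.slope:.2f} %/fraction, r^2 = {lin.r_squared:.4f}, "
          f"max residual {lin.max_abs_residual:.2f}% "
          f"-> {'linear' if lin.passed else 'NOT linear'}")

    plan = classify_fractions(profiles, ratio_tol=0.3)
    print(f"pooling: free RNA = fractions {plan.free_fractions}, "
          f"buffer = {plan.buffer_zone}, polysomal = {plan.polysomal_fractions}, "
          f"discarded = {sorted(plan.discarded)}")

    pio.write_pooling_plan(plan, OUT / "pooling_plan.tsv")
    (OUT / "linearity.json").write_text(json.dumps(vars(lin), indent=2))


if __name__ == "__main__":
    main()
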