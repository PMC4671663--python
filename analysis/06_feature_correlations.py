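"""Correlate audio features with mean colour patches under familywise
control.

Every variable is Box-Cox transformed before Pearson correlation; cells
are tiered at the Dunn-Sidak-corrected level and at nominal 0.05.
"""

import argparse

import pandas as pd

from soundhue.pipeline import RunConfig, run


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results/run")
    ap.add_argument("--m", type=int, default=None,
                    help="familywise correction divisor (default: cell count)")
    args = ap.parse_args()

    cfg = RunConfig(out_dir=args.out, m_comparisons=args.m,
                    stages=("correlations",))
    outs = run(cfg)
    cells = pd.read_csv(outs["correlations"])
    fw = cells[cells["tier"] == "pass-familywise"]
    nom = cells[cells["tier"] == "nominal"]
    print(f"{len(cells)} feature x parameter cells: "
          f"{len(fw)} familywise-significant, {len(nom)} nominal")
    if len(fw):
        print(fw.sort_values("r", ascending=False).to_string(index=False))


if __name__ == "__main__":
    main()
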