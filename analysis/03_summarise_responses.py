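"""Summarise each response envelope into one colour patch.

The late part of each stream is what the participant settled on: the
weighting curve zeroes the first half, ramps to the three-quarter
point, then holds, and the weighted (Size, L, a, b) average over
pen-down samples is the patch association.  Per-stimulus means across
participants feed the stimulus-level analyses.
"""

import argparse

import pandas as pd

from soundhue.pipeline import RunConfig, run


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results/run")
    args = ap.parse_args()

    cfg = RunConfig(out_dir=args.out, stages=("process",))
    outs = run(cfg)
    patches = pd.read_csv(outs["patches"])
    pm = pd.read_csv(outs["patches_mean"])
    print(f"{len(patches)} participant x stimulus patches; "
          f"{len(pm)} per-stimulus means")
    print(pm.head().to_string(index=False))


if __name__ == "__main__":
    main()
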