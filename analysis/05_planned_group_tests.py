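"""Planned nonparametric tests on the extreme-emotion groups.

Kruskal-Wallis across the five discrete emotions with Tukey HSD
follow-up, Wilcoxon rank-sum for the high/low dimensional and
Preference contrasts (with Cohen's d), bootstrap median CIs, and the
male/female patch-size comparison.
"""

import argparse

import pandas as pd

from soundhue.pipeline import RunConfig, run


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results/run")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg = RunConfig(out_dir=args.out, seed=args.seed, stages=("tests",))
    outs = run(cfg)

    disc = pd.read_csv(outs["tests_discrete"])
    print("discrete emotions (Kruskal-Wallis chi2 per colour parameter):")
    print(disc.to_string(index=False))
    dim = pd.read_csv(outs["tests_dimensional"])
    sig = dim[dim["p"] < 0.05]
    print(f"\ndimensional/Preference contrasts: {len(sig)}/{len(dim)} "
          f"significant at 0.05")
    print(sig.to_string(index=False))
    gen = pd.read_csv(outs["tests_gender"])
    print("\ngender comparison (Wilcoxon rank-sum):")
    print(gen.to_string(index=False))


if __name__ == "__main__":
    main()
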