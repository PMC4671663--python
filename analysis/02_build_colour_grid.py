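"""Build the hybrid CIE Lab response space and report its census.

The Lab box is discretised at two-unit resolution; each cell is tested
against the sRGB/D65 display gamut, and invisible cells borrow the
nearest visible colour so the whole physical input range stays
meaningful.
"""

import argparse

from soundhue.pipeline import RunConfig, run


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results/run")
    ap.add_argument("--step", type=float, default=2.0)
    args = ap.parse_args()

    cfg = RunConfig(out_dir=args.out, grid_step=args.step, stages=("grid",))
    outs = run(cfg)
    import json
    stats = json.load(open(outs["grid_stats"]))
    print(f"hybrid grid at step {stats['step']:g}: {stats['cells']:,} cells, "
          f"{stats['visible']:,} visible colours "
          f"({100 * stats['invisible_fraction']:.1f}% borrow their colour)")


if __name__ == "__main__":
    main()
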