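"""Inter-rater agreement per colour parameter and discordant-rater
exclusion.

Cronbach's alpha (participants as items, stimuli as cases) is computed
per parameter; participants whose a* responses correlate negatively
with the consensus are excluded from all four parameters.
"""

import argparse
import json

from soundhue.pipeline import RunConfig, run


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results/run")
    args = ap.parse_args()

    cfg = RunConfig(out_dir=args.out, stages=("agreement",))
    outs = run(cfg)
    reports = json.load(open(outs["agreement"]))
    excluded = reports[0]["excluded"]
    print(f"excluded participants (screened on a*): {excluded or 'none'}")
    for r in reports:
        after = r["alpha_after"]
        print(f"  {r['parameter']:>4}: alpha = {r['alpha']:.2f} ({r['label']})"
              + (f" -> {after:.2f} after exclusion" if excluded else ""))


if __name__ == "__main__":
    main()
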