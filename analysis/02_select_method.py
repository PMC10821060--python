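#!/usr/bin/env python
"""Per-participant method selection on the lab sessions.

For every participant simulated by 01_simulate.py, evaluates the full
method grid (channel combinations x normalization x warping windows) on
their lab trials: discernability max-p from the one-sided Welch test of
within-type vs between-type DTW distances, then leave-one-trial-out
accuracy, then the documented preference rule.  Writes the per-method
table and the selection trace to results/selection/<participant>.json.
"""

import argparse
import json
from pathlib import Path

from wristdtw.data_io import read_session
from wristdtw.method_selection import default_grid, select_method

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    out_dir = ROOT / "selection"
    out_dir.mkdir(parents=True, exist_ok=True)
    for pdir in sorted((ROOT / "sessions").iterdir()):
        lab = read_session(pdir / "lab" / "manifest.json")
        lab.validate_lab_reference()
        result = select_method(lab, default_grid(), alpha=args.alpha)
        out = out_dir / f"{lab.participant_id}.json"
        with open(out, "w") as fh:
            json.dump(result.to_dict(), fh, indent=1, sort_keys=True)
        n_pass = sum(
            1 for r in result.records if r.feasible and r.p_max < args.alpha
        )
        print(
            f"{lab.participant_id}: {n_pass}/{len(result.records)} methods passed "
            f"alpha={args.alpha}; selected {result.selected.label()}"
        )


if __name__ == "__main__":
    main()
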