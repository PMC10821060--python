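#!/usr/bin/env python
"""Generate the synthetic study cohort.

Each participant gets a labeled lab session (per task: 6 correct trials
plus 3 trials of each of two compensatory movement types) and an
unlabeled 75-trial-per-task home session whose ground truth is written to
a separate table — mirroring a protocol where a therapist labels lab
trials live and home trials from video review.

Writes trial CSVs, session manifests and truth tables under
results/sessions/<participant>/.
"""

import argparse
from pathlib import Path

from wristdtw.data_io import write_session
from wristdtw.synthetic import SyntheticConfig, simulate_participant

RESULTS = Path(__file__).resolve().parents[1] / "results" / "sessions"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--participants", type=int, default=3)
    args = ap.parse_args()

    for k in range(args.participants):
        pid = f"P{k + 1:02d}"
        cfg = SyntheticConfig(participant_id=pid)
        lab, home, truth = simulate_participant(cfg, args.seed + k)
        base = RESULTS / pid
        write_session(lab, base / "lab")
        write_session(home, base / "home", truth=truth)
        n_incorrect = int((truth.quality == "incorrect").sum())
        print(
            f"{pid}: {len(lab.trials)} lab trials, {len(home.trials)} home trials "
            f"({n_incorrect} incorrect at home) -> {base}"
        )


if __name__ == "__main__":
    main()
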