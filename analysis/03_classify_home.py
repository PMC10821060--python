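#!/usr/bin/env python
"""Classify each participant's home session and score against truth.

Applies the method chosen by 02_select_method.py: every home trial is
labeled with the quality of its nearest lab trial (projected DTW
distance, home trial as the test series).  Writes per-participant
reports plus a pooled summary to results/reports/.
"""

import json
from pathlib import Path

import pandas as pd

from wristdtw.classification import ConfusionMatrix, classify_session, score_session
from wristdtw.data_io import read_session, write_report
from wristdtw.method_selection import MethodConfig, group_lab_by_task
from wristdtw.synthetic import truth_mapping

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out_dir = ROOT / "reports"
    out_dir.mkdir(parents=True, exist_ok=True)
    pooled = ConfusionMatrix()
    for pdir in sorted((ROOT / "sessions").iterdir()):
        pid = pdir.name
        lab = read_session(pdir / "lab" / "manifest.json")
        home = read_session(pdir / "home" / "manifest.json")
        with open(ROOT / "selection" / f"{pid}.json") as fh:
            sel = json.load(fh)["selected"]
        method = MethodConfig(
            tuple(sel["channels"]), sel["normalize"], sel["window_w"]
        )
        lab_tasks = group_lab_by_task(lab)
        preds = classify_session(home, lab_tasks, method)
        truth = truth_mapping(pd.read_csv(pdir / "home" / "truth.csv"))
        report = score_session(preds, truth, method=method)
        write_report(report, out_dir / f"{pid}.json")
        pooled = pooled + report.overall
        print(
            f"{pid}: accuracy {report.accuracy:.3f}, F1 {report.f1:.3f} "
            f"({report.overall.total} trials, {report.n_unclassifiable} unclassifiable)"
        )
    print(
        f"pooled: accuracy {pooled.accuracy:.3f}, F1 {pooled.f1:.3f} "
        f"over {pooled.total} home trials"
    )


if __name__ == "__main__":
    main()
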