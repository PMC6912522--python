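"""Grade the calibrated BP models against the AAMI, BHS and IEEE standards.

Predicts BP for every beat pair, pools the errors, computes ME/SDE/MAD and
the cumulative error percentages, and writes the evaluation reports (JSON)
plus a human-readable performance table under results/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, load_series

from patbp.evaluation import evaluate_model, report_text, write_report
from patbp.modeling import CalibratedLinearModel


def main() -> None:
    series = load_series()
    reports = {}
    for target in ("sbp", "dbp"):
        model = CalibratedLinearModel.from_dict(
            json.loads((RESULTS / f"model_{target}.json").read_text()))
        report = evaluate_model(model, series)
        write_report(report, RESULTS / f"evaluation_{target}.json")
        report.per_subject.round(4).to_csv(
            RESULTS / f"evaluation_{target}_per_subject.csv", index=False)
        reports[target] = report
    text = report_text(reports)
    (RESULTS / "performance_table.txt").write_text(text + "\n")
    print(text)


if __name__ == "__main__":
    main()
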