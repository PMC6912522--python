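"""Fit the per-subject mean-calibrated linear BP model on PAT_PPG_4.

Pools every subject's mean-centered (PAT, BP) beat pairs, fits the single
slope alpha1 for SBP and for DBP, and serializes each model (slope plus
per-subject calibration means) to JSON under results/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, load_series

from patbp.modeling import fit_calibrated_model, pairs_from_series


def main() -> None:
    series = load_series()
    for target in ("sbp", "dbp"):
        pairs = pairs_from_series(series, target=target)
        model = fit_calibrated_model(pairs, target=target)
        out = RESULTS / f"model_{target}.json"
        out.write_text(json.dumps(model.to_dict(), indent=1, sort_keys=True)
                       + "\n")
        print(f"{target.upper()}: alpha1 = {model.alpha1:.4f} mmHg/ms "
              f"({len(pairs)} pairs, {len(model.per_subject)} subjects) "
              f"-> {out.name}")


if __name__ == "__main__":
    main()
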