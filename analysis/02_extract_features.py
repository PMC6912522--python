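"""Run the full beat-by-beat extraction over the simulated cohort.

Reads the records written by 01, runs baseline removal, R-peak detection,
recording gating, ensemble averaging, fiducial detection and the six
plausibility conditions, and writes one beat table per accepted subject
under scratch/beats/ plus the exclusion summary under results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import BEATS_DIR, COHORT_DIR, RESULTS, subject_ids

from patbp.io import read_record, write_beat_table
from patbp.pipeline import process_record
from patbp.studies import study_pipeline_config


def main() -> None:
    BEATS_DIR.mkdir(parents=True, exist_ok=True)
    config = study_pipeline_config()
    rows = []
    for sid in subject_ids():
        record = read_record(COHORT_DIR / sid)
        result = process_record(record, config)
        n_valid = result.series.n_valid if result.series else 0
        rows.append(f"{sid},{int(result.accepted)},{result.reason or ''},"
                    f"{n_valid},{len(result.beats)}")
        if result.accepted:
            write_beat_table(result.beats, BEATS_DIR / f"{sid}_beats.csv")
        print(f"{sid}: accepted={result.accepted} valid={n_valid} "
              f"rejects={dict(result.reject_counts)}", file=sys.stderr)
    out = RESULTS / "exclusions.csv"
    out.write_text("subject_id,accepted,reason,n_valid,n_beats_total\n"
                   + "\n".join(rows) + "\n")
    print(f"wrote {out}", file=sys.stderr)


if __name__ == "__main__":
    main()
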