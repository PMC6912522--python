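"""Generate the synthetic study cohort and persist it in the record format.

Writes one ECG/PPG/ABP record (CSV + JSON sidecar) and one ground-truth
beat table per subject under scratch/cohort/, plus the cohort metadata
table under results/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import COHORT_DIR, DURATION_S, N_SUBJECTS, RESULTS, SEED

from patbp.io import write_ground_truth, write_record
from patbp.studies import make_study_cohort


def main() -> None:
    COHORT_DIR.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    cohort = make_study_cohort(N_SUBJECTS, seed=SEED, duration_s=DURATION_S)
    rows = []
    for subj in cohort:
        write_record(subj.record, COHORT_DIR / subj.subject_id)
        write_ground_truth(subj.truth.to_frame(),
                           COHORT_DIR / f"{subj.subject_id}_truth.csv")
        rows.append({"subject_id": subj.subject_id, **subj.metadata,
                     "n_beats": subj.truth.n_beats,
                     "sbp_min": round(subj.truth.true_sbp.min(), 1),
                     "sbp_max": round(subj.truth.true_sbp.max(), 1)})
        print(f"{subj.subject_id}: {subj.truth.n_beats} beats, "
              f"SBP {rows[-1]['sbp_min']}-{rows[-1]['sbp_max']} mmHg, "
              f"age {subj.metadata['age']}", file=sys.stderr)
    meta = pd.DataFrame(rows)
    meta.to_csv(RESULTS / "cohort_metadata.csv", index=False)
    print(f"wrote {len(cohort)} records to {COHORT_DIR}", file=sys.stderr)


if __name__ == "__main__":
    main()
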