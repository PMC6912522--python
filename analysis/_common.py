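"""Shared paths and loaders for the numbered analysis drivers.

The drivers form a chain: simulated waveforms and per-subject beat tables
live under ``scratch/`` (large, regenerable), summary tables under
``results/`` (small, text).  Every driver can be re-run from the repository
root, and the whole chain is deterministic under ``SEED``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
COHORT_DIR = SCRATCH / "cohort"
BEATS_DIR = SCRATCH / "beats"

SEED = 42
N_SUBJECTS = 12
DURATION_S = 1200.0  # 20 min per record


def subject_ids() -> list[str]:
    return sorted(p.stem for p in COHORT_DIR.glob("subj*.json"))


def load_series():
    """Rebuild the smoothed per-subject series from the saved beat tables."""
    from patbp.features import SubjectSeries, build_subject_series
    from patbp.io import read_beat_table

    series = []
    for path in sorted(BEATS_DIR.glob("*_beats.csv")):
        sid = path.stem.removesuffix("_beats")
        built = build_subject_series(sid, read_beat_table(path))
        if isinstance(built, SubjectSeries):
            series.append(built)
    return series


def load_metadata() -> dict[str, dict]:
    df = pd.read_csv(RESULTS / "cohort_metadata.csv")
    return {row["subject_id"]: row.drop("subject_id").to_dict()
            for _, row in df.iterrows()}
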