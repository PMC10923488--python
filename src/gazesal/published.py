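"""Published per-image response counts from the eye-tracking study.

The study's summary table reports, for each of 16 images (10 genetic
conditions and 6 unaffected controls, in presentation order), how many
clinicians and non-clinicians correctly and incorrectly called the image
affected or unaffected, and how many named the specific condition.
These printed counts are bundled here as a study input so the accuracy
and chi-square statistics can be recomputed from them.

Not every image has responses from all 22 participants per group:
eye-tracking results for seven isolated image viewings were discarded.
"""

from __future__ import annotations

import pandas as pd

from .stats import ResponseRecord

__all__ = ["RESPONSE_COUNTS", "response_counts_frame", "expand_to_records"]

# image_id, clinician (correct, incorrect, named), non-clinician (correct, incorrect, named)
RESPONSE_COUNTS = [
    ("WS",           17, 5, 4,   13, 9, 3),
    ("Unaffected-1", 22, 0, 0,   19, 3, 0),
    ("RSTS1",        21, 0, 3,   21, 1, 0),
    ("Unaffected-2", 19, 3, 0,   14, 8, 0),
    ("WHS",          20, 2, 0,   19, 3, 0),
    ("Unaffected-3", 22, 0, 0,   20, 2, 0),
    ("CdLS",         22, 0, 10,  22, 0, 5),
    ("DS",           22, 0, 18,  21, 1, 1),
    ("Unaffected-4", 15, 6, 0,   15, 6, 0),
    ("KS",           19, 3, 11,  13, 9, 2),
    ("NS",           21, 0, 9,   21, 0, 0),
    ("Unaffected-5", 18, 4, 0,   18, 4, 0),
    ("22q11DS",      21, 1, 3,   19, 3, 0),
    ("PWS",          16, 5, 0,   10, 12, 0),
    ("Unaffected-6", 14, 8, 0,   19, 3, 0),
    ("BWS",          8, 13, 1,   5, 17, 0),
]


def response_counts_frame() -> pd.DataFrame:
    """The published counts as a tidy frame (one row per image × group)."""
    rows = []
    for image_id, cc, ci, cn, nc, ni, nn in RESPONSE_COUNTS:
        rows.append({"image_id": image_id, "group": "clinician",
                     "correct": cc, "incorrect": ci, "named_condition": cn})
        rows.append({"image_id": image_id, "group": "nonclinician",
                     "correct": nc, "incorrect": ni, "named_condition": nn})
    return pd.DataFrame(rows)


def expand_to_records() -> list[ResponseRecord]:
    """Expand the published counts into individual response records.

    Participant identities behind the counts are not published, so
    records carry synthetic per-image participant ids; that is sufficient
    for accuracy and chi-square statistics, which only consume counts.
    """
    records: list[ResponseRecord] = []
    for image_id, cc, ci, cn, nc, ni, nn in RESPONSE_COUNTS:
        affected = not image_id.startswith("Unaffected")
        for group, n_corr, n_inc, n_named in (
            ("clinician", cc, ci, cn),
            ("nonclinician", nc, ni, nn),
        ):
            prefix = "C" if group == "clinician" else "N"
            idx = 0
            for _ in range(n_corr):
                records.append(ResponseRecord(
                    participant_id=f"{prefix}{idx:02d}", group=group, image_id=image_id,
                    truth_affected=affected, response_affected=affected,
                    condition_named_correctly=idx < n_named))
                idx += 1
            for _ in range(n_inc):
                records.append(ResponseRecord(
                    participant_id=f"{prefix}{idx:02d}", group=group, image_id=image_id,
                    truth_affected=affected, response_affected=not affected,
                    condition_named_correctly=False))
                idx += 1
    return records
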