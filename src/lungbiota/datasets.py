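"""Published reference values bundled for validation and examples.

The sequencing-yield fixture below transcribes the per-sample read totals
(after trimming, OTU clustering and 16S filtering) printed for a published
nine-subject COPD airway cohort: four sites per subject plus six negative
extraction/sequencing controls. One lung specimen (subject 8) yielded only 35
reads and was dropped at the study's rarefaction depth of 563. Note that the
36 subject-sample values sum to 12,667,006 while the source table's own footer
prints a total of 12,667,009; the three-read disagreement is internal to the
published table, so the column sum is the reproducible quantity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .community import OtuTable, SampleMetadata

__all__ = [
    "reference_depths",
    "reference_depth_table",
    "RAREFACTION_DEPTH",
]

#: rarefaction depth used by the reference cohort
RAREFACTION_DEPTH = 563

# (subject, site, reads); subjects 1-3 were sequenced in the first run,
# subjects 4-9 in the second
_REFERENCE_DEPTHS: list[tuple[str, str, int]] = [
    ("1", "oral", 1_179_919), ("1", "nasal", 730_412), ("1", "bronchial", 8_380), ("1", "lung", 5_978),
    ("2", "oral", 1_682_345), ("2", "nasal", 26_571), ("2", "bronchial", 2_811), ("2", "lung", 4_270),
    ("3", "oral", 1_907_839), ("3", "nasal", 818_142), ("3", "bronchial", 10_906), ("3", "lung", 4_104),
    ("4", "oral", 697_399), ("4", "nasal", 342_890), ("4", "bronchial", 1_050), ("4", "lung", 1_068),
    ("5", "oral", 574_101), ("5", "nasal", 562_469), ("5", "bronchial", 582), ("5", "lung", 684),
    ("6", "oral", 463_259), ("6", "nasal", 253_711), ("6", "bronchial", 691), ("6", "lung", 563),
    ("7", "oral", 868_523), ("7", "nasal", 378_236), ("7", "bronchial", 859), ("7", "lung", 931),
    ("8", "oral", 638_699), ("8", "nasal", 439_653), ("8", "bronchial", 1_103), ("8", "lung", 35),
    ("9", "oral", 789_718), ("9", "nasal", 264_946), ("9", "bronchial", 2_161), ("9", "lung", 1_998),
    ("", "control", 115), ("", "control", 820), ("", "control", 103),
    ("", "control", 75), ("", "control", 134), ("", "control", 111),
]


def reference_depths() -> pd.DataFrame:
    """The reference cohort's per-sample read totals as a tidy frame."""
    return pd.DataFrame(_REFERENCE_DEPTHS, columns=["subject_id", "site", "reads"])


def reference_depth_table() -> tuple[OtuTable, SampleMetadata]:
    """The reference depths as a single-taxon OTU table plus metadata.

    Collapsing each sample to one pseudo-taxon carrying its full read total is
    sufficient for depth summaries and rarefaction-threshold bookkeeping.
    """
    rows = []
    ctrl = 0
    for subj, site, reads in _REFERENCE_DEPTHS:
        if site == "control":
            ctrl += 1
            sid, batch = f"control_{ctrl}", "run1" if ctrl <= 3 else "run2"
        else:
            sid = f"S{int(subj):02d}_{site}"
            batch = "run1" if int(subj) <= 3 else "run2"
            subj = f"S{int(subj):02d}"
        rows.append((sid, subj, site, batch, reads))
    sample_ids = [r[0] for r in rows]
    counts = np.array([[r[4] for r in rows]], dtype=np.int64)
    table = OtuTable(["total_reads"], sample_ids, counts)
    metadata = SampleMetadata(
        pd.DataFrame(
            [(r[0], r[1], r[2], r[3]) for r in rows],
            columns=["sample_id", "subject_id", "site", "batch"],
        )
    )
    return table, metadata
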