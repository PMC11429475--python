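"""Five-way glaucoma grading labels and the published dataset ledgers.

The classification target is a five-class glaucoma grade used by the merged
SMDG-19 fundus collection: ``glaucoma``, ``normal``, ``POAG/NTG`` (primary
open-angle / normal-tension glaucoma), ``referable`` and ``suspect``.  The
per-dataset class counts and the augmentation / generation budgets are kept
here as package constants so that manifest bookkeeping can be exercised
without the external image collection.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class ClassLabel:
    """One of the five glaucoma grades, with a stable integer code."""

    code: int
    name: str

    def __post_init__(self) -> None:
        if self.name not in _NAME_TO_CODE:
            raise ValueError(f"unknown class label {self.name!r}")
        if _NAME_TO_CODE[self.name] != self.code:
            raise ValueError(f"label {self.name!r} must carry code {_NAME_TO_CODE[self.name]}")


_NAME_TO_CODE = {
    "glaucoma": 0,
    "normal": 1,
    "POAG/NTG": 2,
    "referable": 3,
    "suspect": 4,
}

GLAUCOMA = ClassLabel(0, "glaucoma")
NORMAL = ClassLabel(1, "normal")
POAG_NTG = ClassLabel(2, "POAG/NTG")
REFERABLE = ClassLabel(3, "referable")
SUSPECT = ClassLabel(4, "suspect")

ALL_LABELS: tuple[ClassLabel, ...] = (GLAUCOMA, NORMAL, POAG_NTG, REFERABLE, SUSPECT)
N_CLASSES = len(ALL_LABELS)


def label_by_name(name: str) -> ClassLabel:
    try:
        return ALL_LABELS[_NAME_TO_CODE[name]]
    except KeyError:
        raise ValueError(f"unknown class label {name!r}") from None


def label_by_code(code: int) -> ClassLabel:
    if not 0 <= code < N_CLASSES:
        raise ValueError(f"class code must be in 0..{N_CLASSES - 1}, got {code}")
    return ALL_LABELS[code]


# Per-dataset class counts of the SMDG-19 merge (rows: class, columns: source
# dataset).  "-" entries in the published overview are zeros here.  The grand
# total is 11,665 images.
SMDG_SOURCE_COUNTS: dict[str, dict[str, int]] = {
    "CRFO-v4": {"glaucoma": 48, "normal": 31},
    "BEH": {"glaucoma": 172, "normal": 462},
    "DRISHTI-GS": {"glaucoma": 70, "normal": 31},
    "Eye-PACS": {"referable": 3270},
    "JSIEC": {"normal": 38, "suspect": 11},
    "G1020": {"glaucoma": 296, "normal": 724},
    "REFUGE": {"glaucoma": 400, "normal": 359, "POAG/NTG": 40},
    "ODIA-ODIR": {"glaucoma": 346, "normal": 4302, "suspect": 14},
    "sjchoi86": {"glaucoma": 101, "normal": 300},
    "ORIGA": {"glaucoma": 165, "normal": 485},
}

# Generation-phase ledger: per-class original-train counts, classical
# augmentation budgets, conditional-GAN generation budgets, and the combined
# training totals.  Note the suspect original-train count (27) disagrees with
# the SMDG source table's suspect sum (25); both ledgers are kept as published
# and the pipeline logs the discrepancy instead of resolving it.
GENERATION_LEDGER: dict[str, dict[str, int]] = {
    "glaucoma": {"original_train": 1598, "augmented": 4794, "cvgan": 1000, "combined": 5794},
    "normal": {"original_train": 6732, "augmented": 8530, "cvgan": 2000, "combined": 10530},
    "POAG/NTG": {"original_train": 40, "augmented": 120, "cvgan": 20, "combined": 140},
    "suspect": {"original_train": 27, "augmented": 108, "cvgan": 15, "combined": 123},
    "referable": {"original_train": 3270, "augmented": 6540, "cvgan": 1000, "combined": 7540},
}


def smdg_class_totals() -> dict[str, int]:
    """Per-class image counts summed over the SMDG source datasets."""
    totals = {lab.name: 0 for lab in ALL_LABELS}
    for counts in SMDG_SOURCE_COUNTS.values():
        for name, n in counts.items():
            totals[name] += n
    return totals
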