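"""Illustrative default code lists.

The chronic-condition list used in real analyses (the HCUP Chronic
Condition Indicator) is licensed content and is therefore an *input* to
this package; the list below is a small, hand-picked illustrative default
spanning the ICD-10 chapters A-Q so that tests and synthetic studies have
a realistic chronic universe out of the box.  Codes are 3-character
ICD-10 category codes.
"""

from __future__ import annotations

# ~60 chronic ICD-10 category codes across chapters (illustrative, not HCUP).
DEFAULT_CHRONIC_CODES: tuple[str, ...] = (
    "A15", "B18",
    "C34", "C50", "C61",
    "D50", "D61", "D64",
    "E03", "E05", "E10", "E11", "E55", "E66", "E77", "E78",
    "F20", "F32", "F41", "F45",
    "G20", "G30", "G35", "G40", "G47",
    "H25", "H40", "H90",
    "I10", "I11", "I15", "I20", "I25", "I27", "I42", "I48", "I50",
    "I63", "I67", "I69", "I70", "I83",
    "J42", "J44", "J45", "J47",
    "K21", "K25", "K50", "K51", "K70", "K74", "K76",
    "L40",
    "M05", "M10", "M15", "M32", "M45", "M47", "M81",
    "N03", "N04", "N18", "N25", "N40", "N80", "N97",
    "Q21",
)

# Acute / non-chronic codes used as admission fillers in the generator;
# they survive the A00-R99 screen but are absent from the chronic list.
DEFAULT_ACUTE_CODES: tuple[str, ...] = (
    "A09", "H10", "J03", "J06", "J18", "K35", "L03", "N39",
)

# Codes that only occur in one sex; conflicting records flag data errors.
DEFAULT_SEX_SPECIFIC: dict[str, str] = {
    "C61": "M",  # prostate cancer
    "N40": "M",  # prostatic hyperplasia
    "N41": "M",  # prostatitis
    "C53": "F",  # cervical cancer
    "N80": "F",  # endometriosis
    "N95": "F",  # menopausal disorders
    "N97": "F",  # female infertility
}

# General-symptom codes used when injecting symptom-only admissions.
SYMPTOM_CODES: tuple[str, ...] = (
    "R05", "R07", "R10", "R42", "R50", "R51", "R53", "R55",
)

# Default operationalization of "general symptoms": the whole R chapter.
DEFAULT_SYMPTOM_PREFIXES: frozenset[str] = frozenset({"R"})
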