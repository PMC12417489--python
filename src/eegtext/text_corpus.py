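"""Clinical report parsing, section selection, task labels and class prompts.

Reports are split on the 15 canonical section headers used in TUH-style
abnormal-EEG reports. Four binary decoding tasks are derived per recording:
pathological status, age over 50, gender, and anticonvulsant medication
(keyword match anywhere in the report).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "SECTION_NAMES",
    "PREAMBLE",
    "TASKS",
    "MEDICATION_KEYWORDS",
    "ClinicalReport",
    "TaskLabelSet",
    "parse_report",
    "render_report",
    "select_sections",
    "derive_labels",
    "build_prompts",
]

#: Canonical section names, in conventional report order.
SECTION_NAMES: tuple[str, ...] = (
    "clinical history",
    "medications",
    "introduction",
    "description of the record",
    "heart rate",
    "findings",
    "impression",
    "clinical correlation",
    "reason for study",
    "technical difficulties",
    "events",
    "condition of the recording",
    "past medical history",
    "type of study",
    "activation procedures",
)

PREAMBLE = "preamble"

TASKS = ("pathological", "age", "gender", "medication")

#: The three most common anticonvulsants; substring-matched case-insensitively.
MEDICATION_KEYWORDS = ("keppra", "dilantin", "depakote")

#: Header spellings that map onto a canonical section name.
DEFAULT_ALIASES: dict[str, str] = {
    "description": "description of the record",
    "history": "clinical history",
    "hr": "heart rate",
    "medication": "medications",
    "correlation": "clinical correlation",
}


@dataclass
class ClinicalReport:
    """Ordered map of canonical section name -> text (possibly empty)."""

    sections: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        allowed = set(SECTION_NAMES) | {PREAMBLE}
        unknown = set(self.sections) - allowed
        if unknown:
            raise ValueError(f"unknown section names: {sorted(unknown)}")

    def get(self, name: str) -> str:
        return self.sections.get(name.lower(), "")

    def non_empty(self) -> dict[str, str]:
        return {k: v for k, v in self.sections.items() if v.strip()}


@dataclass(frozen=True)
class TaskLabelSet:
    pathological: bool | None
    age_over_50: bool | None
    gender: str | None           # "M" | "F"
    medication: bool

    def for_task(self, task: str) -> bool | None:
        if task == "pathological":
            return self.pathological
        if task == "age":
            return self.age_over_50
        if task == "gender":
            return None if self.gender is None else self.gender == "F"
        if task == "medication":
            return self.medication
        raise ValueError(f"unknown task {task!r}")


def _header_pattern(aliases: dict[str, str] | None) -> re.Pattern:
    names = list(SECTION_NAMES) + sorted(aliases or {}, key=len, reverse=True)
    alternatives = "|".join(re.escape(n) for n in sorted(names, key=len, reverse=True))
    return re.compile(rf"^[ \t]*({alternatives})[ \t]*:", re.IGNORECASE | re.MULTILINE)


def parse_report(raw: str, aliases: dict[str, str] | None = None) -> ClinicalReport:
    """Split raw report text on canonical (or aliased) colon-terminated headers.

    Text before the first header lands in the reserved ``"preamble"`` key;
    a header occurring twice has its contents concatenated in order.
    """
    if aliases is None:
        aliases = DEFAULT_ALIASES
    sections: dict[str, str] = {name: "" for name in SECTION_NAMES}
    sections[PREAMBLE] = ""
    if not raw:
        return ClinicalReport(sections)

    matches = list(_header_pattern(aliases).finditer(raw))
    preamble_end = matches[0].start() if matches else len(raw)
    sections[PREAMBLE] = raw[:preamble_end].strip()
    for i, m in enumerate(matches):
        header = m.group(1).lower()
        canonical = aliases.get(header, header)
        end = matches[i + 1].start() if i + 1 < len(matches) else len(raw)
        chunk = raw[m.end():end].strip()
        if sections[canonical]:
            sections[canonical] = sections[canonical] + " " + chunk
        else:
            sections[canonical] = chunk
    return ClinicalReport(sections)


def render_report(rep: ClinicalReport) -> str:
    """Inverse of :func:`parse_report` on non-empty sections (canonical headers)."""
    parts = []
    preamble = rep.sections.get(PREAMBLE, "")
    if preamble.strip():
        parts.append(preamble.strip())
    for name in SECTION_NAMES:
        text = rep.sections.get(name, "")
        if text.strip():
            parts.append(f"{name.upper()}: {text.strip()}")
    return "\n".join(parts)


def select_sections(rep: ClinicalReport, names="all") -> str:
    """Join the selected non-empty sections with blank lines, original order."""
    if names == "all":
        names = SECTION_NAMES
    else:
        bad = [n for n in names if n.lower() not in SECTION_NAMES]
        if bad:
            raise ValueError(f"invalid section names: {bad}")
        order = {n: i for i, n in enumerate(SECTION_NAMES)}
        names = sorted((n.lower() for n in names), key=order.__getitem__)
    chunks = [rep.get(n) for n in names]
    return "\n\n".join(c.strip() for c in chunks if c.strip())


def derive_labels(meta: dict, rep: ClinicalReport | str) -> TaskLabelSet:
    """Derive the four task labels from metadata and the report text.

    Age exactly 50 falls in the non-over class. Medication is a
    case-insensitive substring match over the whole report. Missing metadata
    fields yield ``None`` rather than a guess.
    """
    text = rep if isinstance(rep, str) else render_report(rep)
    lowered = text.lower()
    medication = any(kw in lowered for kw in MEDICATION_KEYWORDS)

    age = meta.get("age")
    if age is not None and int(age) < 0:
        raise ValueError(f"negative age {age}")
    age_over_50 = None if age is None else int(age) > 50

    gender = meta.get("gender")
    if gender is not None and gender not in ("M", "F"):
        raise ValueError(f"gender must be 'M' or 'F', got {gender!r}")

    pathological = meta.get("pathological")
    if pathological is not None:
        pathological = bool(pathological)

    return TaskLabelSet(pathological=pathological, age_over_50=age_over_50,
                        gender=gender, medication=medication)


#: Per-task class prompts; class A listed first, class B second.
_PROMPTS: dict[str, dict[str, str]] = {
    "pathological": {
        "A": "This is a normal recording",
        "B": "This is an abnormal recording",
    },
    "age": {
        "A": "The patient is under 50 years old",
        "B": "The patient is over 50 years old",
    },
    "gender": {
        "A": "The patient is male",
        "B": "The patient is female",
    },
    "medication": {
        "A": "No anti-epileptic drugs were prescribed to the patient",
        "B": "Anti-epileptic drugs were prescribed to the patient",
    },
}


def build_prompts(task: str) -> dict[str, str]:
    """Return the {class: prompt} pair for a task; class B is the positive class."""
    if task not in _PROMPTS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    return dict(_PROMPTS[task])
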