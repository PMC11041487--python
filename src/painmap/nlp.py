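"""Rule-based extraction of pain labels from consultation notes.

The extractor scans the whole note for pain mentions, scores each
mention on a 0-10 scale (numeric patterns like ``7/10`` take precedence
over verbal severity terms in the same sentence), filters out mentions
made in hypothetical, conditional or historical context, keeps negated
mentions at severity 0 (a denial is evidence of "no pain", not absence
of documentation), and summarizes a note as:

* **API** (average pain intensity) — the mean of retained severities;
* **VDP** (verbally declared pain) — ``"pain"`` iff API > 0, else
  ``"no_pain"``.

A note with no retained mention is "pain not documented" and raises
:class:`PainNotDocumented` rather than receiving a label.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "PainMention",
    "PainAnnotation",
    "PainLexicon",
    "PainNotDocumented",
    "find_mentions",
    "filter_context",
    "compute_api",
    "assign_vdp",
    "annotate_note",
    "annotate_directory",
]


class PainNotDocumented(ValueError):
    """No current pain mention was retained for the note."""


@dataclass
class PainMention:
    span: tuple                    # (start, end) character offsets in the note
    surface: str
    severity_score: float          # 0-10
    context_flags: set = field(default_factory=set)

    def __post_init__(self):
        if not 0.0 <= self.severity_score <= 10.0:
            raise ValueError("severity_score must lie in [0, 10]")


@dataclass(frozen=True)
class PainAnnotation:
    api: float
    vdp: str                       # "pain" | "no_pain"
    n_mentions_retained: int
    n_mentions_filtered: int


@dataclass
class PainLexicon:
    """Severity vocabulary and context trigger lists.

    The verbal-grade map mirrors a 4-grade verbal rating scale
    (no pain / mild / moderate / severe); only the sign of the score
    matters for the binary VDP label, so the positive values are a
    convention and are configurable.
    """

    verbal_severity: dict = field(default_factory=lambda: {
        "no": 0.0, "mild": 2.0, "moderate": 5.0, "severe": 8.0,
    })
    bare_severity: float = 5.0     # "pain" with no stated grade
    numeric_pattern: str = r"\b(\d{1,2})\s*(?:/|out\s+of)\s*10\b"
    negation_triggers: tuple = (
        "no", "denies", "denied", "without", "not", "negative for", "free of",
    )
    hypothetical_triggers: tuple = (
        "if", "should", "in case", "risk of", "may", "might", "could", "would",
    )
    conditional_triggers: tuple = (
        "as needed", "prn", "when", "unless", "breakthrough", "upon",
    )
    historical_triggers: tuple = (
        "history of", "last year", "last month", "years ago", "months ago",
        "weeks ago", "previously", "in the past", "prior", "had",
    )
    history_headers: tuple = ("past medical history", "past history")

    def __post_init__(self):
        for term, v in self.verbal_severity.items():
            if not 0.0 <= v <= 10.0:
                raise ValueError(f"verbal severity for {term!r} outside [0, 10]")
        for name in ("negation_triggers", "hypothetical_triggers",
                     "conditional_triggers", "historical_triggers"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be nonempty")

    @classmethod
    def from_json(cls, path) -> "PainLexicon":
        data = json.loads(Path(path).read_text())
        kwargs = {}
        for k in ("verbal_severity", "bare_severity", "numeric_pattern"):
            if k in data:
                kwargs[k] = data[k]
        for k in ("negation_triggers", "hypothetical_triggers",
                  "conditional_triggers", "historical_triggers", "history_headers"):
            if k in data:
                kwargs[k] = tuple(data[k])
        return cls(**kwargs)


_SENT_SPLIT = re.compile(r"[.?!;\n]")
_PAIN = re.compile(r"\bpain(?:ful|s)?\b", re.IGNORECASE)


def _sentences(note: str):
    """Yield (start, end) spans of sentences, split on ``.?!;`` and newline."""
    start = 0
    for m in _SENT_SPLIT.finditer(note):
        yield start, m.start()
        start = m.end()
    if start < len(note):
        yield start, len(note)


def _contains_trigger(text: str, triggers) -> bool:
    low = text.lower()
    return any(re.search(r"\b" + re.escape(t) + r"\b", low) for t in triggers)


def _context_flags(sentence: str, mention_offset: int, lexicon: PainLexicon,
                   in_history_section: bool) -> set:
    before = sentence[:mention_offset]
    flags = set()
    if _contains_trigger(before, lexicon.negation_triggers):
        flags.add("negated")
    if _contains_trigger(before, lexicon.hypothetical_triggers):
        flags.add("hypothetical")
    if _contains_trigger(sentence, lexicon.conditional_triggers):
        flags.add("conditional")
    if in_history_section or _contains_trigger(sentence, lexicon.historical_triggers):
        flags.add("historical")
    return flags


def find_mentions(note: str, lexicon: PainLexicon | None = None) -> list[PainMention]:
    """Locate and score every pain mention in the note.

    Scanning covers the entire note.  Within one sentence, numeric
    scores (``7/10``, ``7 out of 10``) take precedence: verbal mentions
    co-occurring with a numeric score are suppressed.
    """
    if not note:
        raise ValueError("note is empty")
    lexicon = lexicon or PainLexicon()
    numeric_re = re.compile(lexicon.numeric_pattern, re.IGNORECASE)
    mentions: list[PainMention] = []
    in_history = False
    for s_start, s_end in _sentences(note):
        sent = note[s_start:s_end]
        stripped = sent.strip().lower().rstrip(":").strip()
        if stripped in lexicon.history_headers:
            in_history = True
            continue
        if sent.strip().endswith(":"):
            # any other section header ends a history section
            in_history = False
            continue
        pain_hits = list(_PAIN.finditer(sent))
        if not pain_hits:
            continue
        numeric_hits = list(numeric_re.finditer(sent))
        if numeric_hits:
            for m in numeric_hits:
                score = min(float(m.group(1)), 10.0)
                flags = _context_flags(sent, m.start(), lexicon, in_history)
                mentions.append(PainMention(
                    span=(s_start + m.start(), s_start + m.end()),
                    surface=m.group(0),
                    severity_score=score,
                    context_flags=flags,
                ))
            continue
        for m in pain_hits:
            # look back a few tokens for a verbal severity grade
            prefix = sent[:m.start()]
            tokens = re.findall(r"[A-Za-z]+", prefix.lower())[-3:]
            score = lexicon.bare_severity
            surface = m.group(0)
            for t in tokens:
                if t in lexicon.verbal_severity:
                    score = lexicon.verbal_severity[t]
                    surface = f"{t} {m.group(0)}"
                    break
            flags = _context_flags(sent, m.start(), lexicon, in_history)
            if "negated" in flags:
                score = 0.0
            mentions.append(PainMention(
                span=(s_start + m.start(), s_start + m.end()),
                surface=surface,
                severity_score=score,
                context_flags=flags,
            ))
    return mentions


def filter_context(mentions: list[PainMention], note: str = "") -> list[PainMention]:
    """Apply the context rules.

    Hypothetical, conditional and historical mentions are dropped;
    negated mentions are retained with severity forced to 0.  The
    operation is idempotent.
    """
    out = []
    for m in mentions:
        if m.context_flags & {"hypothetical", "conditional", "historical"}:
            continue
        if "negated" in m.context_flags:
            m = PainMention(m.span, m.surface, 0.0, set(m.context_flags))
        out.append(m)
    return out


def compute_api(retained: list[PainMention]) -> float:
    """Average pain intensity: the mean of the retained severity scores."""
    if not retained:
        raise PainNotDocumented("no retained pain mention in note")
    return float(sum(m.severity_score for m in retained) / len(retained))


def assign_vdp(api: float) -> str:
    """Binary verbally-declared-pain label: ``pain`` iff API > 0."""
    if not 0.0 <= api <= 10.0:
        raise ValueError("api must lie in [0, 10]")
    return "pain" if api > 0 else "no_pain"


def annotate_note(note: str, lexicon: PainLexicon | None = None) -> PainAnnotation:
    """find_mentions -> filter_context -> compute_api -> assign_vdp."""
    mentions = find_mentions(note, lexicon)
    retained = filter_context(mentions, note)
    api = compute_api(retained)
    return PainAnnotation(
        api=api,
        vdp=assign_vdp(api),
        n_mentions_retained=len(retained),
        n_mentions_filtered=len(mentions) - len(retained),
    )


def annotate_directory(notes_dir, lexicon: PainLexicon | None = None) -> pd.DataFrame:
    """Annotate every ``*.txt`` note in a directory.

    Returns a table ``patient_id, api, vdp, n_retained, n_filtered``;
    notes without documented pain are reported with ``vdp = "not_documented"``.
    """
    notes_dir = Path(notes_dir)
    if not notes_dir.is_dir():
        raise FileNotFoundError(f"notes directory not found: {notes_dir}")
    rows = []
    for path in sorted(notes_dir.glob("*.txt")):
        pid = path.stem
        try:
            ann = annotate_note(path.read_text(), lexicon)
            rows.append({"patient_id": pid, "api": ann.api, "vdp": ann.vdp,
                         "n_retained": ann.n_mentions_retained,
                         "n_filtered": ann.n_mentions_filtered})
        except PainNotDocumented:
            rows.append({"patient_id": pid, "api": float("nan"),
                         "vdp": "not_documented", "n_retained": 0,
                         "n_filtered": 0})
    return pd.DataFrame(rows)
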