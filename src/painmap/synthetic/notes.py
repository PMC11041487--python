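"""Templated radiation-oncology consultation notes with known pain truth.

Each note contains exactly one valid *current* pain statement (or an
explicit denial for painless notes) plus a configurable number of
distractor sentences — negated, hypothetical, conditional or historical
pain mentions that a correct extractor must ignore.
"""

from __future__ import annotations

import numpy as np

__all__ = ["generate_note", "SEVERITIES", "SEVERITY_NUMERIC"]

SEVERITIES = ("none", "mild", "moderate", "severe")

# a numeric pain score consistent with each verbal grade, used when the
# template phrases the current pain numerically
SEVERITY_NUMERIC = {"mild": 3, "moderate": 5, "severe": 8}

_CURRENT_VERBAL = [
    "The patient reports {sev} pain in the thoracic spine.",
    "She describes {sev} pain over the mid back today.",
    "He complains of {sev} pain at the treatment site.",
    "On examination there is {sev} pain localized to the thoracic region.",
]

_CURRENT_NUMERIC = [
    "Pain today is rated {num}/10 in the back.",
    "The patient rates the pain at {num} out of 10.",
    "Current pain score is {num}/10.",
]

_DENIAL = [
    "The patient denies pain at this visit.",
    "She reports no pain today.",
    "He is currently without pain.",
]

_DISTRACTORS = [
    # hypothetical
    "If pain worsens, the patient will contact the clinic.",
    "Should severe pain develop, we will escalate analgesia.",
    "We discussed the risk of pain progressing after treatment.",
    # conditional
    "Analgesics are to be taken as needed for pain.",
    "Breakthrough pain medication was prescribed prn.",
    # historical
    "The patient had severe pain last year before radiotherapy.",
    "There is a history of chronic back pain several years ago.",
    "She previously experienced moderate pain, which resolved.",
]

_FILLER = [
    "The patient was seen in consultation for palliative radiotherapy.",
    "Imaging demonstrates metastatic disease involving the thoracic spine.",
    "Treatment options were discussed with the patient and family.",
    "The plan is a short course of external beam radiotherapy.",
    "The patient tolerated the consultation well.",
]


def generate_note(pain_status: bool, severity: str, distractors: int = 0,
                  seed: int = 0) -> str:
    """Generate one consultation note.

    ``severity`` must be ``"none"`` iff ``pain_status`` is False.  The
    note contains one valid current-pain statement (a denial when
    painless), ``distractors`` ignorable pain mentions, and filler
    sentences; deterministic given ``seed``.
    """
    if (severity == "none") != (not pain_status):
        raise ValueError("severity must be 'none' exactly when pain_status is False")
    if severity not in SEVERITIES:
        raise ValueError(f"severity must be one of {SEVERITIES}")
    rng = np.random.default_rng(seed)

    if not pain_status:
        key = _DENIAL[rng.integers(len(_DENIAL))]
    elif rng.random() < 0.5:
        key = _CURRENT_VERBAL[rng.integers(len(_CURRENT_VERBAL))].format(sev=severity)
    else:
        num = SEVERITY_NUMERIC[severity]
        key = _CURRENT_NUMERIC[rng.integers(len(_CURRENT_NUMERIC))].format(num=num)

    chosen = [str(_DISTRACTORS[i]) for i in
              rng.choice(len(_DISTRACTORS), size=min(distractors, len(_DISTRACTORS)),
                         replace=False)]
    while len(chosen) < distractors:
        chosen.append(str(_DISTRACTORS[rng.integers(len(_DISTRACTORS))]))

    body = [_FILLER[rng.integers(len(_FILLER))], key]
    body.extend(chosen)
    body.append(_FILLER[rng.integers(len(_FILLER))])
    order = list(range(len(body)))
    # keep the first filler first; shuffle the rest for variety
    tail = order[1:]
    rng.shuffle(tail)
    body = [body[0]] + [body[i] for i in tail]
    return "\n".join(body) + "\n"
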