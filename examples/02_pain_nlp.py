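"""Extract API / VDP pain labels from consultation-note text.

Each note is scanned for pain mentions; hypothetical, conditional and
historical mentions are filtered; denials are kept at severity 0.  The
API (average pain intensity, 0-10) is the mean retained severity and
VDP (verbally declared pain) is "pain" iff API > 0.
"""

from painmap.nlp import annotate_note, filter_context, find_mentions

note = """The patient was seen for palliative radiotherapy.
He had severe pain last year before treatment.
If pain worsens, he will contact the clinic.
Current pain score is 6/10.
Analgesics to be taken as needed for pain.
"""

mentions = find_mentions(note)
for m in mentions:
    print(f"  {m.surface!r:28} severity={m.severity_score:<4} flags={sorted(m.context_flags)}")
kept = filter_context(mentions)
print(f"retained {len(kept)} of {len(mentions)} mentions")

ann = annotate_note(note)
print(f"API = {ann.api}   VDP = {ann.vdp}")
# Only the current 6/10 score survives the context rules, so the note is
# labeled pain with API 6.0.
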