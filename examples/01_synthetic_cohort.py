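"""Generate a small synthetic cohort and inspect what was planted.

Builds 6 phantom note-image pairs: each patient gets a CT phantom with
lesions planted in a bone cylinder, a consultation note whose pain
wording matches the lesions' shared pain status, and truth tables.
"""

import tempfile
from pathlib import Path

import pandas as pd

from painmap.synthetic import CohortSpec, generate_cohort

out = Path(tempfile.mkdtemp()) / "cohort"
spec = CohortSpec(n_patients=6, pain_fraction=0.6, seed=0)
paths = generate_cohort(spec, out)

truth = pd.read_csv(paths.truth_csv)
print(f"wrote {len(list(paths.volumes_dir.glob('*.nrrd')))} volumes, "
      f"{len(truth)} lesions")
print(truth.to_string(index=False))
print(f"\npainful lesion fraction: {truth['painful'].mean():.2f}")
print("\nfirst note:\n" + (paths.notes_dir / "P000.txt").read_text())
# Every lesion of one image shares the image's pain status; the note's
# wording encodes the same truth the NLP stage must recover.
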