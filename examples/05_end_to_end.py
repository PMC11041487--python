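"""One-command end-to-end run: synthesize -> NLP -> ROI -> features -> train.

Equivalent to ``painmap demo``.  Takes a couple of minutes on one CPU.
"""

import tempfile
from pathlib import Path

from painmap import pipeline

out = Path(tempfile.mkdtemp()) / "run"
out.mkdir(parents=True)
cfg = out / "config.yaml"
cfg.write_text(
    "cohort:\n  n_patients: 10\n  pain_fraction: 0.7\n  seed: 0\n"
    "ml:\n  seed: 0\n")

manifest = pipeline.run_end_to_end(cfg, out)
for stage, info in manifest["stages"].items():
    print(f"  {stage:<12} {info['seconds']:7.1f} s")
print()
print(pipeline.report(out))
# The grid shows test AUC / F1 for 4 classifiers x 2 ensembles; on this
# tiny demo the numbers are noisy — the test suite uses ~200 lesions.
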