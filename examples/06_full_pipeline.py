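"""Run the whole pipeline (simulate -> preprocess -> stats -> decompose ->
classify) with one seeded config, writing every artifact to a run directory."""

import json
import tempfile
from pathlib import Path

import chickspec as cs

out = Path(tempfile.mkdtemp()) / "run"
config = cs.RunConfig(seed=1, out_dir=str(out))
run_dir = cs.run_pipeline(config)

metrics = json.loads((run_dir / "summary.json").read_text())
print(json.dumps(metrics, indent=2))
print(f"-> all spectra, statistics, decompositions and confusion matrices "
      f"were written under {run_dir}; rerunning with the same seed "
      f"reproduces summary.json byte for byte.")
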