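"""End-to-end synthetic run: simulate -> bin -> wavefront -> qpcr ->
splice -> coupling, with a manifest and a per-stage report.

Equivalent shell command:  polwave run-all --seed 3 --out runs/demo
"""
import tempfile
from pathlib import Path

from polwave.pipeline import RunConfig, report, run_all

out_dir = Path(tempfile.mkdtemp()) / "demo"
config = RunConfig(seed=3)
run_all(config, out_dir)
print(report(out_dir))
print(f"stage outputs and manifest written under {out_dir}")
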