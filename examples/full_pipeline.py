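"""End-to-end run: synthetic data for every stage through the report pipeline."""

import tempfile
from pathlib import Path

from lynxmon import synthdata
from lynxmon.report import RunConfig, run_pipeline

workdir = Path(tempfile.mkdtemp(prefix="lynxmon_"))
datadir = workdir / "data"
synthdata.write_all(synthdata.SimConfig(seed=1), datadir)

config = RunConfig(
    inputs={
        "genotypes": str(datadir / "genotypes.csv"),
        "traps": str(datadir / "traps.csv"),
        "detections": str(datadir / "detections.csv"),
        "tracks": str(datadir / "tracks.csv"),
        "periods": str(datadir / "periods.csv"),
    },
    params={"scr": {"buffer": 7500.0}},  # simulated grid uses a 7.5 km buffer
    out=str(workdir / "out"),
)
summary = run_pipeline(config)
print((workdir / "out" / "summary.txt").read_text())
for key, value in summary.items():
    print(f"{key}: {value}")
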