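"""Shared locations for the analysis drivers.

Each numbered script reads its inputs from and writes its outputs to
``results/`` at the repository root, so the chain can be re-run step by
step: 01 simulates the multi-study dataset, 02 harmonizes and QC-filters
it, 03 attributes genus origins, 04 compares diversity, 05 runs the
differential-abundance procedure and 06 summarizes prevalence signatures.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SYNTH = RESULTS / "synthetic"
QC = RESULTS / "qc"
ORIGINS = RESULTS / "origins"
DIVERSITY = RESULTS / "diversity"
DIFFABUND = RESULTS / "diffabund"
SIGNATURES = RESULTS / "signatures"

SEED = 1
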