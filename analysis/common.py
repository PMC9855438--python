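"""Shared configuration and paths for the numbered analysis scripts.

The study conditions: 10 tumors per group (PT vs BM), 200 cells per tumor,
1,000 genes, 4 cell clusters with 20 markers each, a 2:1 PT:BM within-tumor
dispersion ratio, group-shifted cell-type composition, and one planted
directional ligand-receptor pair from cluster C0 to C1.
"""

from pathlib import Path

from tmecompare import syndata

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
SIM_DIR = SCRATCH / "sim"
QC_DIR = SCRATCH / "qc"

SEED = 20230116

STUDY_CONFIG = syndata.SimConfig(
    seed=SEED,
    lr_pairs_planted=[("G0151", "G0152", "C0", "C1")],
)
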