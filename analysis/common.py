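"""Shared paths and study constants for the analysis scripts.

Run the scripts in order from the repository root:

    python analysis/01_simulate_data.py
    python analysis/02_contact_and_gam.py
    ...

Every script regenerates nothing: 01 writes the synthetic study inputs
(with their planted truth) under results/data/, and the later stages read
them back through the package's text formats.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "data"     # bulky raw inputs (regenerated by 01)
TABLES = ROOT / "results"            # small summary tables

SEED = 20260928

# study conditions
BIN_SIZE = 200_000
CHROM_LENGTHS = [100_000_000]            # 500 bins, one chromosome for maps
GAM_CHROMS = [10_000_000, 5_000_000]     # 75 bins, diploid structures
SPIN_BIN = 25_000
SPIN_CHROM = [75_000_000]                # 3,000 bins
DEPTH = 1_000_000
COMPARTMENT_STRENGTH = 1.5
TAD_STRENGTH = 3.0
LOOP_FACTOR = 3.0


def ensure_dirs():
    DATA.mkdir(parents=True, exist_ok=True)
    TABLES.mkdir(parents=True, exist_ok=True)
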