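"""Shared paths and parameters for the analysis scripts.

The study-scale run uses the full field design (4 months x 3 depths x
2 hillslope locations x 2 replicates = 48 paired samples) on a 60-genome
community at desk-scale sequencing depth. Bulky intermediates (placement
tables) live under scratch/; the scripts write their summary tables under
results/.
"""

from pathlib import Path

from soilvirome import synth

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

SEED = 20170307  # first sampling date of the field campaign

DESIGN = synth.CommunityDesign(library_size_mean=20_000)

N_VOTUS = 60
LENGTH_RANGE = (5000, 15000)
MOLECULE_MIX = 0.2  # fraction of ssRNA genomes


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
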