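#!/usr/bin/env python
"""Simulate the synthetic seed-bank community for the downstream analyses.

Generates 60 viral genomes (20% ssRNA), plants activity schedules (5%
seasonal DNA subset, half of the rest constitutively active), and simulates
strand-aware read placements for all 96 libraries of the field design with
negative-binomial noise. Bulky outputs go to scratch/analysis; a small
design summary goes to results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd
from common import DESIGN, LENGTH_RANGE, MOLECULE_MIX, N_VOTUS, RESULTS, SCRATCH, SEED, ensure_dirs

from soilvirome import io as svio
from soilvirome import synth


def main() -> None:
    ensure_dirs()
    contigs, genes = synth.generate_genomes(
        N_VOTUS, length_range=LENGTH_RANGE, molecule_mix=MOLECULE_MIX, seed=SEED
    )
    truth = synth.plant_truth(contigs, genes, DESIGN, seed=SEED + 1)
    placements, libraries = synth.simulate_placements(
        truth, DESIGN, contigs, genes, seed=SEED + 2
    )

    svio.write_fasta(contigs, SCRATCH / "genomes.fasta")
    svio.write_gff3(genes, SCRATCH / "genes.gff3")
    svio.write_category_table(genes, SCRATCH / "categories.tsv")
    placements.to_csv(SCRATCH / "placements.tsv", sep="\t", index=False)
    libraries.to_csv(SCRATCH / "libraries.tsv", sep="\t", index=False)
    synth.write_truth_tables(truth, SCRATCH / "truth")
    pd.DataFrame(
        [{"contig_id": c.id, "molecule": c.molecule, "completeness": c.completeness}
         for c in contigs]
    ).to_csv(SCRATCH / "completeness.tsv", sep="\t", index=False)

    n_dna = sum(c.molecule == "DNA" for c in contigs)
    seasonal = [
        v for v, sched in truth.schedule.items()
        if truth.molecule[v] == "DNA" and sum(s != "inactive" for s in sched.values()) == 1
    ]
    summary = pd.DataFrame(
        [
            {"quantity": "genomes", "value": len(contigs)},
            {"quantity": "dna_genomes", "value": n_dna},
            {"quantity": "ssrna_genomes", "value": len(contigs) - n_dna},
            {"quantity": "genes", "value": len(genes)},
            {"quantity": "libraries", "value": len(libraries)},
            {"quantity": "total_read_placements", "value": len(placements)},
            {"quantity": "seasonal_dna_votus_planted", "value": len(seasonal)},
        ]
    )
    summary.to_csv(RESULTS / "01_simulation_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"\nwrote placements for {len(libraries)} libraries to {SCRATCH}")


if __name__ == "__main__":
    main()
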