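#!/usr/bin/env python
"""Build the vOTU catalog from a redundant contig set.

Takes the simulated genomes, adds near-identical mutated copies and
sub-fragments (the redundancy an assembly of many libraries produces), runs
the length/completeness retention filter, and clusters at 95% ANI / 85% AF
with longest-member representatives. The catalog should collapse every
derived copy back onto its source genome.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import numpy as np
import pandas as pd
from common import RESULTS, SCRATCH, SEED, ensure_dirs

from soilvirome import io as svio
from soilvirome.catalog import ViralContig, cluster_contigs, retention_filter


def mutate(seq: str, rate: float, rng) -> str:
    seq = list(seq)
    for pos in rng.choice(len(seq), size=int(rate * len(seq)), replace=False):
        seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
    return "".join(seq)


def main() -> None:
    ensure_dirs()
    rng = np.random.default_rng(SEED + 10)
    comp = pd.read_csv(SCRATCH / "completeness.tsv", sep="\t")
    contigs = svio.read_fasta(
        SCRATCH / "genomes.fasta",
        completeness=dict(zip(comp["contig_id"], comp["completeness"])),
        molecule=dict(zip(comp["contig_id"], comp["molecule"])),
    )

    redundant = list(contigs)
    for c in contigs[:30]:  # mutated near-duplicates (~2% divergence)
        redundant.append(
            ViralContig(f"{c.id}_dup", mutate(c.sequence, 0.02, rng), c.molecule, None)
        )
    for c in contigs[10:40]:  # 90% sub-fragments with low completeness
        cut = int(0.9 * c.length)
        redundant.append(
            ViralContig(f"{c.id}_frag", c.sequence[:cut], c.molecule, 40.0)
        )
    for c in contigs[:5]:  # short low-completeness fragments: should be dropped
        redundant.append(ViralContig(f"{c.id}_short", c.sequence[:3000], c.molecule, 20.0))

    retained = retention_filter(redundant)
    votus = cluster_contigs(retained)
    svio.write_votu_table(votus, RESULTS / "02_votus.tsv")

    assignment = {m: v.representative for v in votus for m in v.members}
    collapsed = sum(
        1
        for m, rep in assignment.items()
        if ("_dup" in m or "_frag" in m) and m.split("_dup")[0].split("_frag")[0] == rep
    )
    derived = sum(1 for m in assignment if "_dup" in m or "_frag" in m)
    summary = pd.DataFrame(
        [
            {"quantity": "input_contigs", "value": len(redundant)},
            {"quantity": "retained_after_filter", "value": len(retained)},
            {"quantity": "dropped_by_filter", "value": len(redundant) - len(retained)},
            {"quantity": "votus", "value": len(votus)},
            {"quantity": "derived_copies_clustered_to_source", "value": collapsed},
            {"quantity": "derived_copies_total", "value": derived},
        ]
    )
    summary.to_csv(RESULTS / "02_votu_catalog_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
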