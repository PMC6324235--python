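#!/usr/bin/env python
"""Simulate the study system and write its data files.

Generates the realistic four-genome scenario — the shared ancient
hexaploidization, a durian-lineage hexaploidization, a cotton-lineage
decaploidization with a strongly elevated cotton substitution rate, plus
gene loss, tandem duplication and rearrangement — and writes per-genome
CDS FASTA, BED gene orders, all-vs-all hit tables and the ground truth
under results/data/.
"""

import json
from pathlib import Path

from ploidyscan import simulate

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 42

config = simulate.scenario("study", n_ancestral_genes=150, seed=SEED)
genomes, truth, sequences = simulate.simulate_all(config, OUT)

sizes = {taxon: len(table) for taxon, table in genomes.items()}
print(f"wrote {OUT}")
print("gene counts per genome:", sizes)
print("events:", [(e.name, e.branch, e.multiplicity) for e in config.events])
(OUT / "scenario.json").write_text(json.dumps(
    {"scenario": "study", "seed": SEED, "n_ancestral_genes": 150,
     "gene_counts": sizes}, indent=2))
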