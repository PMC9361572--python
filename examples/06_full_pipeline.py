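"""Full pipeline run: simulate CDS pairs, then kaks -> date -> assign.

Writes the stage TSVs plus a run-metadata JSON into ./pipeline_demo/
and prints the per-interval pair counts.
"""

import json
import tempfile
from pathlib import Path

from ksdater import PairSimSpec, RunConfig, run_pipeline, simulate_codon_pair

workdir = Path(tempfile.mkdtemp(prefix="ksdater_demo_"))
fasta = workdir / "cds.fasta"
pairs = workdir / "pairs.tsv"
with open(fasta, "w") as fa, open(pairs, "w") as pr:
    for i, ks in enumerate([0.1, 0.45, 0.62, 0.95, 1.6]):
        pair, _ = simulate_codon_pair(
            PairSimSpec(n_codons=200, target_ks=ks, omega=0.2, seed=i)
        )
        fa.write(f">gA{i}\n{pair.seq_a}\n>gB{i}\n{pair.seq_b}\n")
        pr.write(f"gA{i}\tgB{i}\n")

config = RunConfig(
    cds=str(fasta), pairs=str(pairs), genome="celery", rate=5.2e-9,
    rate_name="apiaceae",
)
outdir = run_pipeline(config, workdir / "out")

meta = json.loads((outdir / "run_metadata.json").read_text())
print("stage outputs:", sorted(p.name for p in outdir.iterdir()))
print("interval counts:", meta["interval_counts"])
print()
print(
    "Five pairs simulated at Ks 0.1 .. 1.6 spread across the anchor\n"
    "intervals as their divergence dictates; rerunning with the same\n"
    "config reproduces the TSVs byte for byte."
)
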