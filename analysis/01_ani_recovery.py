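#!/usr/bin/env python
"""How well does gene-based ANI recover true genome divergence?

Simulates genome pairs over a divergence grid, compares them with the
reciprocal-best-hit gene engine, and tabulates estimated ANI against
the simulator's exact identity.  Writes results/ani_recovery.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from speciesgap import pairwise, simgen


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--seeds", type=int, default=3)
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    params = pairwise.PairwiseParams(codon_alignments=False)
    rows = []
    for divergence in (0.01, 0.03, 0.05, 0.10, 0.15):
        for seed in range(1, args.seeds + 1):
            config = simgen.PairSimConfig(
                n_genes=100, gene_length_mean=300, divergence=divergence,
                omega=0.5, seed=seed)
            genome_a, genome_b, truth = simgen.simulate_pair(config)
            result = pairwise.compare_genomes(genome_a, genome_b, params)
            rows.append({
                "divergence": divergence, "seed": seed,
                "true_identity": truth.true_identity,
                "estimated_ani": result.ani,
                "abs_error": abs(result.ani - truth.true_identity),
                "n_genes_aligned": result.n_genes_aligned,
                "alignment_fraction": result.alignment_fraction,
            })
    df = pd.DataFrame(rows)
    out = args.outdir / "ani_recovery.tsv"
    df.to_csv(out, sep="\t", index=False, float_format="%.6f")
    print(f"wrote {out}")
    print(f"max |estimated ANI - truth| = {df.abs_error.max():.6f} "
          f"over {len(df)} simulated pairs (tolerance of interest: 0.002)")


if __name__ == "__main__":
    main()
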