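#!/usr/bin/env python
"""Does genome-wide Nei-Gojobori dN/dS recover the simulated selection
regime?

Simulates pairs at 5% divergence under three nonsynonymous-acceptance
settings (omega 0.1 / 0.3 / 1.0 — strong purifying selection to
neutrality), estimates dN/dS from codon alignments of the RBH genes,
and compares against the ratio counted directly from the simulator's
substitution log.  Writes results/dnds_recovery.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from speciesgap import evometrics, pairwise, simgen


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--seeds", type=int, default=3)
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for omega in (0.1, 0.3, 1.0):
        for seed in range(1, args.seeds + 1):
            config = simgen.PairSimConfig(
                n_genes=200, gene_length_mean=300, divergence=0.05,
                omega=omega, seed=seed)
            genome_a, genome_b, truth = simgen.simulate_pair(config)
            result = pairwise.compare_genomes(genome_a, genome_b)
            est = evometrics.pair_dnds(result)
            rows.append({
                "omega": omega, "seed": seed,
                "true_dnds_counted": truth.true_dnds,
                "estimated_dnds": est.dnds,
                "rel_error": abs(est.dnds / truth.true_dnds - 1.0),
                "syn_subs": est.counts.syn_subs,
                "nonsyn_subs": est.counts.nonsyn_subs,
            })
    df = pd.DataFrame(rows)
    out = args.outdir / "dnds_recovery.tsv"
    df.to_csv(out, sep="\t", index=False, float_format="%.6f")
    print(f"wrote {out}")
    summary = df.groupby("omega")[["true_dnds_counted", "estimated_dnds",
                                   "rel_error"]].mean()
    print(summary.to_string(float_format="%.4f"))
    print(f"max relative error {df.rel_error.max():.3f} "
          f"(band of interest: 0.15); estimates rank with omega: "
          f"{summary.estimated_dnds.is_monotonic_increasing}")


if __name__ == "__main__":
    main()
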