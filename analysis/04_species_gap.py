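#!/usr/bin/env python
"""The species gap: ANI landscape and F1-optimal delineation threshold.

Simulates a 3-species population with a constructed identity gap
(within-species >= 97%, between-species <= 90%), runs the all-vs-all
gene-based comparison, summarizes the ANI x alignment-fraction
landscape, and scans identity thresholds for the F1-optimal species
boundary.  Writes results/population_pairs.tsv, results/threshold_scan.tsv
and results/landscape_summary.tsv.
"""

import argparse
import itertools
from pathlib import Path

import pandas as pd

from speciesgap import delineation, evometrics, pairwise, seqio, simgen


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    spec = simgen.PopulationSpec(
        n_species=3, genomes_per_species=4,
        within_identity_range=(0.97, 0.995), between_identity_max=0.90,
        n_genes=60, gene_length_mean=300, seed=args.seed)
    genomes, labels, truth = simgen.generate_population(spec)
    params = pairwise.PairwiseParams(codon_alignments=False)
    rows = []
    for ga, gb in itertools.combinations(genomes, 2):
        result = pairwise.compare_genomes(ga, gb, params)
        rows.append(evometrics.pair_metrics_row(result))
    seqio.write_pair_table(rows, args.outdir / "population_pairs.tsv")
    df = seqio.read_pair_table(args.outdir / "population_pairs.tsv")
    print(f"wrote {args.outdir / 'population_pairs.tsv'} ({len(df)} pairs)")

    grid = delineation.ani_landscape(df, grid_size=80, pad=3.0)
    peaks = (grid.density > 0.5 * grid.density.max()).sum()
    pd.DataFrame({
        "quantity": ["integral", "bandwidth_factor", "n_cells_above_half_max"],
        "value": [grid.integral(), grid.bandwidth, peaks],
    }).to_csv(args.outdir / "landscape_summary.tsv", sep="\t", index=False)
    print(f"landscape integral {grid.integral():.4f} "
          f"(two clusters expected: within- and between-species pairs)")

    matrix = delineation.pair_labels_from_taxonomy(labels)
    identities = delineation.identities_from_pair_summaries(df, percent=False)
    scan = delineation.scan_thresholds(identities, matrix)
    scan.to_frame().to_csv(args.outdir / "threshold_scan.tsv", sep="\t",
                           index=False, float_format="%.6f")
    print(f"optimal species threshold {scan.optimal_threshold:.2f}% ANI, "
          f"F1 = {scan.optimal_f1:.3f}; max-F1 plateau "
          f"[{scan.plateau_low:.1f}%, {scan.plateau_high:.1f}%] spans the "
          f"constructed gap (between <= 90%, within >= 97%)")


if __name__ == "__main__":
    main()
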