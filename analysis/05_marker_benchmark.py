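#!/usr/bin/env python
"""Can single genes stand in for whole-genome ANI?

Cuts individual genes out of the simulated gap population and treats
each as a single-copy marker: its pairwise identity matrix is scanned
for the F1-optimal species threshold against both taxonomy labels and
95%-ANI labels, alongside prevalence and a recoverability illustration.
Writes results/marker_benchmark.tsv.
"""

import argparse
import itertools
from pathlib import Path

from speciesgap import delineation, markers, pairwise, simgen
from speciesgap.markers import MarkerHit, MarkerSet


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-markers", type=int, default=4)
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    spec = simgen.PopulationSpec(
        n_species=3, genomes_per_species=4,
        within_identity_range=(0.97, 0.995), between_identity_max=0.90,
        n_genes=60, gene_length_mean=300, seed=args.seed)
    genomes, labels, _truth = simgen.generate_population(spec)
    universe = [g.genome_id for g in genomes]

    marker_sets = []
    for i in range(args.n_markers):
        gene_id = f"g{i:05d}"
        marker_sets.append(MarkerSet(marker_name=f"marker_{gene_id}", hits=[
            MarkerHit(genome_id=g.genome_id, gene_id=gene_id,
                      nt_seq=g[gene_id].nt_seq) for g in genomes]))

    # labels both from taxonomy and from genome-wide 95% ANI
    tax = delineation.pair_labels_from_taxonomy(labels)
    import pandas as pd
    params = pairwise.PairwiseParams(codon_alignments=False)
    pair_rows = []
    for ga, gb in itertools.combinations(genomes, 2):
        res = pairwise.compare_genomes(ga, gb, params)
        pair_rows.append({"genome1": res.genome_a, "genome2": res.genome_b,
                          "ani": 100.0 * res.ani if res.ani else None})
    ani95 = delineation.pair_labels_from_ani(pd.DataFrame(pair_rows))

    rows = markers.marker_benchmark(marker_sets, [tax, ani95], universe)
    recover = {m.marker_name: markers.recoverability(300, 100)
               for m in marker_sets}  # illustrative worked example
    table = markers.benchmark_table(rows, recoverabilities=recover)
    out = args.outdir / "marker_benchmark.tsv"
    table.to_csv(out, sep="\t", index=False, float_format="%.4f")
    print(f"wrote {out}")
    print(table.to_string(index=False))
    agree = sum(1 for r in rows if not r.flagged and r.f1 >= 0.9)
    print(f"{agree}/{len(rows)} markers delineate the simulated species at "
          f"F1 >= 0.9; single ~300-nt genes are noisier proxies of the "
          f"genome-wide boundary")


if __name__ == "__main__":
    main()
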