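"""Generate the synthetic study inputs and their truth tables.

Produces a 50-nt read library with planted CAG tracts, a transcriptome of
stitched gene regions with planted CUG tracts (some spanning region
junctions), a ranked gene list with a planted negative shift, and paired
LOI/Ref RISC-bound libraries at 4:1 group-1 abundance.  Everything is
seeded and accompanied by the exact planted truth.
"""

import argparse
from pathlib import Path

from tnrkit import io
from tnrkit.synthetic_data import (
    SimulationSpec,
    synth_ranked_list,
    synth_read_library,
    synth_risc_library,
    synth_transcriptome,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results/sim"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    spec = SimulationSpec(seed=args.seed, n_reads=5000,
                          tract_plan={10: 50, 13: 20, 50: 5})
    reads, truth_hist = synth_read_library(spec)
    io.write_fasta(reads, args.outdir / "reads.fa", collapsed=False)
    with open(args.outdir / "reads_truth.tsv", "w") as out:
        out.write("tract_len\tcount\n")
        for length in sorted(truth_hist):
            out.write(f"{length}\t{truth_hist[length]}\n")
    print(f"reads: {len(reads)} planted plan {spec.tract_plan}")

    tspec = SimulationSpec(seed=args.seed + 1, n_genes=500,
                           tract_plan={length: 10
                                       for length in range(10, 20)})
    records, truth = synth_transcriptome(tspec, unit="CTG")
    io.write_region_table(records, args.outdir / "regions.tsv")
    truth.to_csv(args.outdir / "regions_truth.tsv", sep="\t", index=False)
    print(f"transcriptome: {truth.shape[0]} genes, "
          f"{(truth.planted_tract_len > 0).sum()} with planted CUG tracts")

    rspec = SimulationSpec(seed=args.seed + 2, n_genes=2000,
                           effect_size=-2.0, noise_sd=1.0)
    targets = {f"G{i:05d}" for i in range(100)}
    scores, rank_truth = synth_ranked_list(rspec, targets)
    io.write_rnk(scores, args.outdir / "ranking.rnk")
    rank_truth.to_csv(args.outdir / "ranking_truth.tsv", sep="\t",
                      index=False)
    print(f"ranked list: {len(scores)} genes, shift -2 on {len(targets)}")

    lspec = SimulationSpec(seed=args.seed + 3, n_reads=50_000)
    libraries, lib_truth = synth_risc_library(lspec)
    for name, lib_reads in libraries.items():
        io.write_fasta(lib_reads, args.outdir / f"risc_{name}.fa",
                       collapsed=False)
    lib_truth.to_csv(args.outdir / "risc_truth.tsv", sep="\t", index=False)
    print(f"RISC libraries: {', '.join(libraries)} at "
          f"{lspec.abundance_ratio} group-1 abundance")


if __name__ == "__main__":
    main()
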