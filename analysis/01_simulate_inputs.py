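#!/usr/bin/env python
"""Generate the synthetic study inputs every later stage consumes.

Writes, under results/sim/:
  * focal/reference KO copy-number matrices (TSV) + MAG metadata (TSV)
  * an ANI matrix with a planted replicate structure (TSV)
  * 30 annotated genomes (gene-table TSVs + contig FASTAs), 20 carrying a
    planted steroid gene cluster and 10 negatives
  * one variant table (VCF) per cluster-bearing genome
  * the truth tables for all of the above
"""

import argparse
from pathlib import Path

import pandas as pd

from spongemag.config import setup_logging
from spongemag.io import write_fasta, write_gene_table, write_matrix, write_vcf
from spongemag.simulate import (
    CohortSpec,
    GenomeSpec,
    VariantSpec,
    default_planted_effects,
    gen_ani,
    gen_cohort,
    gen_genome,
    gen_variants,
)

HERE = Path(__file__).resolve().parents[1]


def mag_table(mags):
    return pd.DataFrame(
        [
            {
                "mag_id": m.mag_id,
                "source_group": m.source_group,
                "phylum": m.phylum,
                "class_": m.class_,
                "completeness": m.completeness,
                "contamination": m.contamination,
                "quality": m.quality,
                "total_proteins": m.total_proteins,
            }
            for m in mags
        ]
    ).set_index("mag_id")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=HERE / "results" / "sim")
    args = ap.parse_args()
    setup_logging()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    # --- two-group cohort for the enrichment analysis -----------------------
    effects = default_planted_effects(30, 30, seed=args.seed)
    cohort = gen_cohort(
        CohortSpec(n_features=2060, planted_effects=effects, seed=args.seed)
    )
    write_matrix(cohort["focal_counts"], out / "focal_ko_counts.tsv")
    write_matrix(cohort["reference_counts"], out / "reference_ko_counts.tsv")
    mag_table(cohort["focal_mags"]).to_csv(out / "focal_mags.tsv", sep="\t")
    mag_table(cohort["reference_mags"]).to_csv(out / "reference_mags.tsv", sep="\t")
    cohort["truth"].to_csv(out / "truth_enrichment.tsv", sep="\t", index=False)
    print(
        f"cohort: {len(cohort['focal_mags'])} host-associated vs "
        f"{len(cohort['reference_mags'])} free-living MAGs, "
        f"{cohort['focal_counts'].shape[1]} features, "
        f"{len(cohort['truth'])} planted effects"
    )

    # --- ANI matrix with planted replicate clusters --------------------------
    focal_ids = [m.mag_id for m in cohort["focal_mags"]]
    ani, ani_truth = gen_ani(focal_ids, n_clusters=25, seed=args.seed)
    ani.to_csv(out / "focal_ani.tsv", sep="\t")
    pd.Series(ani_truth, name="cluster").to_csv(out / "truth_ani.tsv", sep="\t")
    print(f"ANI matrix: {len(focal_ids)} MAGs, 25 planted replicate clusters")

    # --- genomes with planted steroid clusters ------------------------------
    genome_rows = []
    for k in range(30):
        positive = k < 20
        spec = GenomeSpec(
            genome_id=f"mag{k:02d}",
            plant_cluster=positive,
            plant_negative=not positive,
            cluster_intervening=1 if k % 4 == 0 else 0,
            seed=args.seed * 1000 + k,
        )
        g = gen_genome(spec)
        write_gene_table(g["genes"], out / f"mag{k:02d}_genes.tsv")
        write_fasta(g["contigs"], out / f"mag{k:02d}_contigs.fasta")
        for t in g["truth"]:
            genome_rows.append({"genome_id": spec.genome_id, **{
                kk: v for kk, v in t.items() if kk != "sequence"}})
        if positive:
            sites, vtruth = gen_variants(
                g["genes"],
                VariantSpec(
                    low_rate_genes=("ERG24", "CYP51", "ERG7"),
                    seed=args.seed * 1000 + k,
                ),
            )
            write_vcf(
                sites,
                out / f"mag{k:02d}.vcf",
                contig_lengths={c: len(s) for c, s in g["contigs"].items()},
            )
            vtruth.to_csv(
                out / f"mag{k:02d}_truth_variants.tsv", sep="\t", index=False
            )
    pd.DataFrame(genome_rows).to_csv(
        out / "truth_clusters.tsv", sep="\t", index=False
    )
    print("genomes: 20 cluster-positive (with VCFs) + 10 negatives written")
    print(f"all inputs under {out}")


if __name__ == "__main__":
    main()
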