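"""Genotype mtDNA variants through the filter stack.

Reads the dataset from 01, gates cells on quality >= 0.75, applies the
strand-support (>= 2 alternate reads per strand, pseudo-bulk),
strand-concordance (forward/reverse heteroplasmy Pearson R >= 0.2) and
homopolymer-blacklist (513-525, 3105-3109) filters, and writes the VCF plus
per-cell heteroplasmy/depth matrices for the PASS variants.

  python analysis/02_genotype_variants.py [--outdir results]
"""

import argparse
from pathlib import Path

from mitodlp import copynum, genotyping
from mitodlp.simulate import read_dataset


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cells, counts, truth = read_dataset(args.outdir / "dataset")
    gated, gate = copynum.quality_gate(cells)
    print(f"quality gate (>= 0.75): kept {gate['kept']} / dropped {gate['dropped']}")

    gcounts = counts[counts["cell_id"].isin(gated["cell_id"])]
    records = genotyping.apply_filter_stack(
        gcounts, reference_length=len(truth.reference), variant_classes=truth.variants
    )
    genotyping.write_vcf(records, args.outdir / "variants.vcf",
                         reference_length=len(truth.reference))
    pass_pos = [r.position for r in records if r.is_pass]
    print(f"variants: {len(records)} called, {len(pass_pos)} PASS")
    for r in records:
        status = "PASS" if r.is_pass else "fail:" + ",".join(
            n for n in genotyping.FILTER_NAMES if n not in r.filters_passed)
        print(f"  m.{r.position}{r.ref}>{r.alt}  pooled h={r.pooled_heteroplasmy:.3f} "
              f"strand R={r.strand_r:.2f}  {status}")

    het, depth = genotyping.genotype_cells(gcounts, pass_pos)
    het.to_csv(args.outdir / "heteroplasmy.tsv", sep="\t", float_format="%.6g")
    depth.to_csv(args.outdir / "depth.tsv", sep="\t")
    labels = genotyping.classify_homoplasmy(het)
    print(f"homoplasmy labels: {labels.value_counts().to_dict()}")


if __name__ == "__main__":
    main()
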