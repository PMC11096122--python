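"""Heteroplasmy / copy-number association and the cell-size regression.

Applies the observation filters (>= 10 alternate reads, heteroplasmy inside
(0.05, 0.95), per-variant range >= 0.15), computes the stratified weighted
concordance of heteroplasmy against copy number per variant with BH-adjusted
q-values, and regresses copy number on cell diameter per library (the slope
is mtDNA copies per micron).

  python analysis/05_heteroplasmy_cn_association.py [--outdir results]
"""

import argparse
from pathlib import Path

import pandas as pd

from mitodlp import assoc
from mitodlp.simulate import read_dataset


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    het = pd.read_csv(args.outdir / "heteroplasmy.tsv", sep="\t", index_col=0)
    depth = pd.read_csv(args.outdir / "depth.tsv", sep="\t", index_col=0)
    pc = pd.read_csv(args.outdir / "percell_cn.tsv", sep="\t", index_col="cell_id")
    _, counts, _ = read_dataset(args.outdir / "dataset")
    altm = (counts.assign(a=counts["fwd_alt"] + counts["rev_alt"])
            .pivot_table(index="cell_id", columns="position", values="a", aggfunc="sum", fill_value=0))
    altm.columns = [str(c) for c in altm.columns]

    common = het.index.intersection(pc.index)
    obs = assoc.concordance_filters(
        het.loc[common], altm.reindex(index=common, columns=het.columns, fill_value=0),
        cn=pc.loc[common, "cn"], strata=pc.loc[common, "library_id"],
    )
    print(f"{len(obs)} / {het.shape[1]} variants enter the concordance test")
    table = assoc.concordance_table(obs)
    table.to_csv(args.outdir / "assoc.tsv", sep="\t", index=False, float_format="%.6g")
    if len(table):
        show = table[["variant", "n_obs", "c_scaled", "z", "p", "q"]]
        print(show.to_string(index=False, float_format=lambda x: f"{x:.3g}"))

    reg = assoc.size_regression(pc.reset_index())
    reg.to_csv(args.outdir / "regression.tsv", sep="\t", index=False, float_format="%.6g")
    for _, row in reg.iterrows():
        if row.get("flag"):
            print(f"  {row['library_id']}: {row['flag']}")
        else:
            print(f"  {row['library_id']}: slope={row['slope']:.1f} copies/um "
                  f"R={row['pearson_r']:.2f} q={row['q']:.2g}")


if __name__ == "__main__":
    main()
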