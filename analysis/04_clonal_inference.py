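"""Clone assignment from mtDNA variants (MityBayes) and nuclear profiles.

Fits the binomial-mixture clone model to the PASS-variant count matrices
(BIC over K = 1..5 chooses the clone number), clusters nuclear bin-state
profiles, and cross-checks the two labelings — diploid and tetraploid cells
of the same clone should share mtDNA variants, so the partitions should
agree.

  python analysis/04_clonal_inference.py [--seed 0] [--outdir results]
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from mitodlp import clones_nu, copynum, mitybayes as mb
from mitodlp.simulate import parse_bin_states, read_dataset


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cells, counts, truth = read_dataset(args.outdir / "dataset")
    gated, _ = copynum.quality_gate(cells)
    vcf = (args.outdir / "variants.vcf").read_text().splitlines()
    pass_pos = [int(l.split("\t")[1]) for l in vcf if not l.startswith("#") and l.split("\t")[6] == "PASS"]
    sub = counts[counts["cell_id"].isin(gated["cell_id"]) & counts["position"].isin(pass_pos)]
    alt = (sub.assign(a=sub["fwd_alt"] + sub["rev_alt"])
           .pivot_table(index="cell_id", columns="position", values="a", aggfunc="sum", fill_value=0))
    tot = (sub.assign(t=sub["fwd_total"] + sub["rev_total"])
           .pivot_table(index="cell_id", columns="position", values="t", aggfunc="sum", fill_value=0))

    k, table = mb.select_k(alt.to_numpy(), tot.to_numpy(), range(1, 6), seed=args.seed, n_restarts=4)
    print("BIC over K:\n" + table.to_string(index=False, float_format=lambda x: f"{x:.1f}"))
    print(f"chosen K = {k}")
    model = mb.fit(alt.to_numpy(), tot.to_numpy(), k, seed=args.seed, n_restarts=8)
    labels = mb.assign_clones(model, min_prob=0.9)
    clones = pd.DataFrame({"cell_id": alt.index, "clone": [str(l) for l in labels],
                           "max_prob": model.gamma.max(axis=1)})
    clones.to_csv(args.outdir / "clones.tsv", sep="\t", index=False, float_format="%.6g")
    print(f"assignments: {clones['clone'].value_counts().to_dict()}")
    contrib = ", ".join(f"m.{p}:{w:.2f}" for p, w in zip(alt.columns, model.contribution))
    print(f"variant contribution weights: {contrib}")

    bins = pd.DataFrame(parse_bin_states(gated), index=gated["cell_id"])
    nu = clones_nu.cluster_cells_nu(bins, n_clones=k, seed=args.seed)
    pd.DataFrame({"cell_id": nu.labels.index, "clone": nu.labels.values,
                  "method": nu.method}).to_csv(args.outdir / "nuclones.tsv", sep="\t", index=False)

    mt_labels = pd.Series(clones["clone"].to_numpy(), index=clones["cell_id"])
    check = clones_nu.crosscheck_clones(nu.labels, mt_labels)
    print(f"nuclear vs mtDNA clone agreement: ARI = {check['ari']:.3f}")
    with open(args.outdir / "crosscheck.json", "w") as fh:
        json.dump({"ari": check["ari"], "n_shared": check["n_shared"],
                   "contingency": {str(k2): v for k2, v in check["contingency"].to_dict().items()}},
                  fh, indent=2)


if __name__ == "__main__":
    main()
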