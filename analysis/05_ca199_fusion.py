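#!/usr/bin/env python
"""Combine the microbiome classifiers with the coded CA19-9 serum marker.

CA19-9 is coded 1 above 37 U/mL (0 for negative or not available).  The OR
combination adds the code to the mean cross-validated score; the AND
combination multiplies.  The complementary serum signal should lift AUROC
over the microbiome-only classifiers, most visibly for the enrichment-
constrained model.
"""

import argparse
from pathlib import Path

import pandas as pd

from pdacmicro import (TrainedEnsemble, combine_and, combine_or, encode_ca199,
                       read_metadata_tsv, roc_evaluate)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--modeldir", type=Path, default=Path("results/models"))
    ap.add_argument("--outdir", type=Path, default=Path("results/fusion"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    meta = read_metadata_tsv(args.datadir / "train_metadata.tsv")
    y = (meta["group"] == "PDAC").to_numpy()
    codes = encode_ca199(meta["ca199_level"])
    print(f"CA19-9 positive: {int(codes[y].sum())}/{y.sum()} PDAC, "
          f"{int(codes[~y].sum())}/{(~y).sum()} controls")

    rows = []
    for variant in ("unconstrained", "enrichment_constrained"):
        ens = TrainedEnsemble.from_json(args.modeldir / f"model_{variant}.json")
        scores = ens.cv_scores.loc[meta.index]
        rows.append({"variant": variant, "combination": "microbiome_only",
                     "auroc": roc_evaluate(scores.to_numpy(), y).auroc})
        for name, fn in (("or", combine_or), ("and", combine_and)):
            fused = fn(scores, codes)
            rows.append({"variant": variant, "combination": name,
                         "auroc": roc_evaluate(fused.to_numpy(), y).auroc})
    out = pd.DataFrame(rows)
    out.to_csv(args.outdir / "fusion_auroc.tsv", sep="\t", index=False)
    print(out.pivot(index="variant", columns="combination", values="auroc")
          .round(3).to_string())


if __name__ == "__main__":
    main()
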