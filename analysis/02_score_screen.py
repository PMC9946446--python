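"""Quantify the screen: normalized resistance scores and enrichment hits.

Reads the count table and design from step 01, runs the
RPM -> +1 -> log2 -> plasmid-normalization -> replicate-averaging ->
control-centering chain, calls hits at the 2-SD negative-control
threshold, and reports how estimated scores track the simulation truth.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from crisprscan import screen_quant


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    counts = pd.read_csv(args.results / "counts.tsv", sep="\t", index_col="sgrna")
    design = dict(
        pd.read_csv(args.results / "design.tsv", sep="\t").itertuples(index=False)
    )
    library = screen_quant.SgRNALibrary.from_table(args.results / "library.tsv")

    scores = screen_quant.compute_resistance_scores(
        counts, design, library.negative_control_ids
    )
    scores.rename_axis("sgrna").to_csv(args.results / "resistance_scores.tsv", sep="\t")

    truth = pd.read_csv(
        args.results / "true_scores.tsv", sep="\t", index_col="sgrna"
    )["true_score"]
    ok = ~scores["excluded"]
    r = np.corrcoef(truth[ok], scores.loc[ok, "score"])[0, 1]
    print(
        f"scored {ok.sum()} sgRNAs ({(~ok).sum()} excluded for zero plasmid reads); "
        f"{int(scores['hit'].sum())} hits; correlation with truth r = {r:.3f}"
    )


if __name__ == "__main__":
    main()
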