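"""Test whether clinically correlated item pairs share a semantic cluster.

Pairs every TLC item with its strongest CLANG correlate across the
simulated participants (after dropping items no one scored above zero),
counts how many pairs land in the same semantic cluster, and runs the
exact one-sided binomial test against flat chance (1 / number of
clusters).  Run 01 and 04 first.
"""

import argparse
import json
from pathlib import Path

from semharm.backbone import read_clusters_tsv
from semharm.clinical import (
    chance_level,
    cocluster_test,
    exclude_degenerate_items,
    load_ratings_csv,
    top_correlate_pairing,
)

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

tlc = load_ratings_csv(args.data / "ratings_TLC.csv", "TLC")
clang = load_ratings_csv(args.data / "ratings_CLANG.csv", "CLANG")
clusters = read_clusters_tsv(args.out / "clusters.tsv")

tlc, zero_tlc, _ = exclude_degenerate_items(tlc)
clang, zero_clang, _ = exclude_degenerate_items(clang)
pairs = top_correlate_pairing(tlc, clang, method="pearson")
chance = chance_level(clusters, rule="flat")
res = cocluster_test(pairs, clusters, chance)

result = {
    "excluded_all_zero": zero_tlc + zero_clang,
    "n_pairs": res.n_pairs,
    "n_cocluster": res.n_cocluster,
    "chance_level": chance,
    "p_value": res.p_value,
    "pairs": [
        {"backbone": p.backbone_item, "partner": p.partner_item,
         "r": p.correlation,
         "cocluster": clusters.labels[p.backbone_item]
                      == clusters.labels[p.partner_item]}
        for p in res.pairs
    ],
}
(args.out / "clinical_alignment.json").write_text(json.dumps(result, indent=2))

print(f"excluded all-zero items: {zero_tlc + zero_clang or 'none'}")
print(f"{res.n_cocluster} of {res.n_pairs} strongest-correlate pairs fall in "
      f"the same semantic cluster (chance {chance:.2f})")
print(f"exact binomial p = {res.p_value:.3g}")
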