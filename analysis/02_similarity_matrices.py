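"""Embed the item bank and build item- and scale-level similarity matrices.

Uses the deterministic mock backend (run 01 first).  Writes the full
item x item cosine matrix and the scale-centroid matrix whose diagonal
holds each scale's within-scale semantic consistency (mean pairwise item
similarity), then prints that diagonal — scales that spread their items
over all four themes show low internal consistency by construction.
"""

import argparse
from pathlib import Path

import numpy as np

from semharm.cli import stage_seed
from semharm.embedding import (
    MockEmbeddingBackend,
    embed_bank,
    item_similarity_matrix,
    scale_centroid_matrix,
    write_similarity_tsv,
)
from semharm.item_bank import load_item_bank, preprocess_bank

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

bank = preprocess_bank(load_item_bank(args.data / "item_bank.csv"))
backend = MockEmbeddingBackend(seed=stage_seed(args.seed, "embed"), dimension=256)
emb = embed_bank(bank, backend)

item_sim = item_similarity_matrix(emb)
write_similarity_tsv(item_sim, args.out / "item_similarity.tsv")
scale_sim = scale_centroid_matrix(emb, bank)
write_similarity_tsv(scale_sim, args.out / "scale_similarity.tsv")

print(f"backend: {backend.backend_id}")
print(f"item similarity: {len(item_sim.ids)} x {len(item_sim.ids)} "
      f"-> {args.out / 'item_similarity.tsv'}")
print("within-scale consistency (scale-matrix diagonal):")
for i, scale in enumerate(scale_sim.ids):
    d = scale_sim.values[i, i]
    print(f"  {scale:<6} {'n/a' if np.isnan(d) else f'{d:.3f}'}")
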