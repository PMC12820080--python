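"""Generate the synthetic study dataset and describe the item corpus.

Writes the item bank, ground-truth theme labels, six simulated expert
raters' assignments, and participant ratings for the two clinically
administered scales under results/data/, then prints per-scale description
lengths — the corpus is deliberately uneven, with two verbose scales and
one terse one, like real instruments.
"""

import argparse
from pathlib import Path

from semharm.item_bank import length_statistics, load_item_bank
from semharm.synthetic import GeneratorConfig, write_dataset

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/data"))
args = parser.parse_args()

config = GeneratorConfig(seed=args.seed)
paths = write_dataset(config, args.out)
bank = load_item_bank(paths["item_bank"])
stats = length_statistics(bank)

print(f"wrote {len(paths)} files to {args.out}")
print(f"{len(bank)} items across {len(bank.scales)} scales")
print("scale  mean_words  max_words")
for scale, mean, mx in stats.to_rows():
    print(f"{scale:<6} {mean:>9.1f} {mx:>10d}")
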