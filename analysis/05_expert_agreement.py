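"""Score expert-machine agreement with Fleiss' kappa.

Folds the machine clustering in as a seventh rater next to the six
simulated experts (after matching anonymous cluster numbers to the experts'
named categories by majority vote) and reports overall and per-category
kappa with asymptotic 95% confidence intervals, plus the items that agree
best and worst with the machine.  Run 01 and 04 first.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from semharm.agreement import (
    build_assignment_matrix,
    category_kappa,
    disagreement_ranking,
    fleiss_kappa,
    majority_machine_map,
)
from semharm.backbone import read_clusters_tsv

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

experts = pd.read_csv(args.data / "expert_assignments.csv", dtype=str)
machine = read_clusters_tsv(args.out / "clusters.tsv")
machine_map = majority_machine_map(experts, machine)

matrix = build_assignment_matrix(experts, machine=machine, machine_map=machine_map)
overall = fleiss_kappa(matrix)
rows = [("overall", overall)]
rows += [(c, category_kappa(matrix, c)) for c in matrix.categories]

ranking = disagreement_ranking(build_assignment_matrix(experts), machine,
                               machine_map=machine_map)

result = {
    "kappa": {name: {"kappa": r.kappa, "se": r.se,
                     "ci": [r.ci_low, r.ci_high]} for name, r in rows},
    "best_agreed": ranking[:3],
    "most_disagreed": ranking[-3:][::-1],
}
(args.out / "agreement.json").write_text(json.dumps(result, indent=2))

print(f"{matrix.n_raters} raters (6 experts + machine), "
      f"{len(matrix.items)} items, {len(matrix.categories)} categories")
print(f"{'scope':<24} kappa     SE   95% CI")
for name, r in rows:
    print(f"{name:<24} {r.kappa:.3f}  {r.se:.3f}  "
          f"[{r.ci_low:.3f}, {r.ci_high:.3f}]")
print("best human-machine agreement:", [i for i, _ in ranking[:3]])
print("worst human-machine agreement:", [i for i, _ in ranking[-3:]])
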