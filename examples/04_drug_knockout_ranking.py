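"""Knockout simulation: remove one drug's interactions and try to re-find them.

This mirrors how single-drug predictions are assessed: every interaction of
the chosen drug is deleted, the model is refit on the reduced matrix, and
the drug's diseases are ranked by predicted score.  A good model places the
deleted (true) diseases at the top.
"""

import numpy as np

from ddicmf import HyperParams, generate_synthetic, rank_diseases_for_drug

im, s_drug, s_disease = generate_synthetic(
    n=60, m=40, k_true=4, density=0.05, noise=0.0, seed=1
)
counts = im.Y.sum(axis=1)
drug_idx = int(np.flatnonzero(counts == 5)[0])  # a drug with 5 known diseases
drug_id = im.drug_ids[drug_idx]

ranking = rank_diseases_for_drug(
    im, s_drug, s_disease, HyperParams(), drug_id=drug_id, top_n=10
)
print(f"top 10 predicted diseases for {drug_id} "
      f"(its {int(counts[drug_idx])} true interactions were removed):")
for rank, entry in enumerate(ranking, 1):
    tag = "known" if entry.previously_known else "novel"
    print(f"  {rank:2d}. {entry.disease_id}  score={entry.score:.3f}  [{tag}]")
# "known" rows are the deleted true interactions re-discovered by the model;
# "novel" rows are candidate repositioning hypotheses.
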