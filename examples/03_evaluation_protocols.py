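"""The two evaluation protocols: K-fold CV and the label-ascending split.

K-fold shuffles records into near-equal folds.  The label-ascending split
instead holds out, within every complex, the mutants with the *highest*
ΔΔG — an extrapolation test: can the model predict affinity losses larger
than any it saw for that complex?
"""

import numpy as np

from seqddg import (
    SyntheticConfig,
    generate_dataset,
    kfold_split,
    label_ascending_split,
    pearson,
    r_squared,
    rank_consistency,
)

dataset, truth = generate_dataset(SyntheticConfig(n_complexes=3, mutations_per_complex=20, seed=1))

plan = kfold_split(dataset, k=5, seed=0)
sizes = np.bincount(plan.assignments)
print(f"5-fold split of {len(dataset)} records -> fold sizes {sizes.tolist()}")

plan = label_ascending_split(dataset, test_fraction=0.2)
for cid in dataset.complex_ids:
    idx = [i for i, r in enumerate(dataset.records) if r.complex_id == cid]
    test = [dataset.records[i].ddg for i in idx if plan.assignments[i] == 1]
    train = [dataset.records[i].ddg for i in idx if plan.assignments[i] == 0]
    print(
        f"{cid}: {len(train)} train / {len(test)} test, "
        f"max train ΔΔG {max(train):+.2f} <= min test ΔΔG {min(test):+.2f}"
    )

# Metrics on a noisy mock predictor (the true signal plus noise), to show
# what each number measures -- no training involved here.
rng = np.random.default_rng(0)
y = np.array([r.ddg for r in dataset.records])
yhat = y + rng.normal(0, 0.8, size=len(y))
print(f"\nmock predictor vs labels (n={len(y)}):")
print(f"  PCC              {pearson(y, yhat):+.3f}")
print(f"  R2               {r_squared(y, yhat):+.3f}")
print(f"  rank consistency {rank_consistency(y, yhat):+.3f} (R2 on rank vectors)")
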