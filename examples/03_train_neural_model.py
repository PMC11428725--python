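"""Train the 3-10-3 sigmoid network on the extraction runs.

The three factor settings predict DPPH, FRAP and TPC simultaneously.
Training is Levenberg-Marquardt on a random 19/4/4 train/validation/test
split with validation-based early stopping; a small topology search picks
the hidden-layer width.
"""

from extractopt import ann_model as am
from extractopt import study_table

table = study_table()

best_h, scores = am.topology_search(table, hidden_sizes=range(8, 13), seeds=range(3))
print("hidden-size search (validation R2, best of 3 seeds):")
print(scores.to_string(index=False))
print(f"selected hidden size: {best_h}")

model = am.train_lm(table, config=am.TrainConfig(hidden_size=best_h, seed=1))
h = model.history
print(f"\nstopped at epoch {h.stopped_epoch}, best validation epoch {h.best_epoch}")
for subset, r in h.subset_r.items():
    print(f"  R({subset}) = {r:.3f}")

edges, counts = am.error_histogram(model, table)
print("\nerror histogram (counts per subset over 20 bins):")
for subset, c in counts.items():
    print(f"  {subset}: {list(map(int, c))}")

# Reading: correlations near 1 on the training subset show the network can
# represent the response surface; the validation/test correlations show how
# far that generalizes from only 27 runs.
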