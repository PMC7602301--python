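"""Train an RBF-SVM m5C predictor on synthetic data and evaluate it on a
held-out split shaped like the small-species benchmark (200+200 training,
69+69 independent test fragments).
"""

import tempfile
from pathlib import Path

from m5cpred import (
    SVMGrid,
    SyntheticSpec,
    cross_validate,
    generate_dataset,
    get_preset,
    load_dataset,
    predict_scores,
    score_report,
    train_on_dataset,
    write_benchmark_layout,
)

spec = SyntheticSpec(
    n_pos=269, n_neg=269, seed=11,
    pwm_effect={18: {"G": 6.5}, 19: {"G": 6.5}, 23: {"A": 6.5}, 24: {"G": 6.5}},
)
data = generate_dataset(spec)
with tempfile.TemporaryDirectory() as tmp:
    paths = write_benchmark_layout(data, Path(tmp), test_fraction=69 / 269, seed=11)
    train = load_dataset(paths["train_pos"], paths["train_neg"], 20)
    test = load_dataset(paths["test_pos"], paths["test_neg"], 20)

feature_spec = get_preset("h_sapiens").feature_spec()
grid = SVMGrid.coarse(4)
print(f"training on {train.n_pos}+{train.n_neg} fragments, "
      f"subset '{feature_spec.name}', {len(grid)}-point grid")

cv = cross_validate(train, feature_spec, grid, folds=10, seed=11)
rep = cv.mean_report()
print(f"10-fold CV: AUROC {rep.AUROC:.3f}, Acc {100 * rep.Acc:.1f}%, "
      f"Mcc {rep.Mcc:.3f} (BC {cv.box_constraint:g}, KS {cv.kernel_scale:g})")

model = train_on_dataset(
    train, feature_spec,
    SVMGrid.single(cv.box_constraint, cv.kernel_scale), seed=11,
)
scores = [s for s, _ in predict_scores(model, test.fragments)]
t = score_report(scores, test.labels)
print(f"independent test ({test.n_pos}+{test.n_neg}): AUROC {t.AUROC:.3f}, "
      f"Acc {100 * t.Acc:.1f}%, Sn {100 * t.Sn:.1f}%, Sp {100 * t.Sp:.1f}%")
print("(CV and test agree because train and test share the generating process)")
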