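"""Train a small quality regressor end to end and evaluate it.

Builds a perturbed phantom corpus, trains the width-reduced two-channel
residual regressor for a few epochs, and reports held-out regression and
accept/decline classification metrics at the 0.6 IoU threshold.
Runtime: a few minutes on one CPU core.
"""
from glottisqc import LossParams
from glottisqc.studies import make_perturbed_corpus, train_quality_model

train_set, test_set = make_perturbed_corpus(n_train=600, n_test=200, seed=3)
res = train_quality_model(train_set, test_set, LossParams(0.5, 0.5, 0.6),
                          seed=3, epochs=8)
print(f"held-out MSE       : {res['mse']:.4f}   (squared error of predicted IoU)")
print(f"held-out accuracy  : {res['accuracy']:.3f}   (accept/decline at t=0.6)")
print(f"specificity        : {res['specificity']:.3f}   (true-accept rate)")
print(f"sensitivity        : {res['sensitivity']:.3f}   (failure-detection rate)")
print(f"MAE on failed cases: {res['mae_below_t']:.3f}   (stratum with true IoU < 0.6)")
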