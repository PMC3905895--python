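"""Fit the eRNA logistic regression and read its coefficients.

The model is  logit p_j = beta0 + sum_i beta_i x_ij  on standardized
log densities. On the synthetic defaults the activating acetylations come
out with positive weights and the repressive H3K27me3 with a negative one.
"""

from example_utils import build_small_dataset

from ernapredict import fit_logistic, predict_proba
from ernapredict.metrics import auc_score, mcc_at_threshold

data = build_small_dataset(seed=11)
model = fit_logistic(data.signal, data.labels)
print(f"converged in {model.n_iter} Newton steps, "
      f"log-likelihood {model.loglik:.1f}")
print(f"{'mark':<12}{'beta (std)':>12}{'beta (raw)':>12}")
for mark, b_std, b_raw in zip(model.marks, model.beta, model.raw_beta):
    print(f"{mark:<12}{b_std:>12.3f}{b_raw:>12.3f}")

p = predict_proba(model, data.signal.subset_rows(data.labels.training_ids))
y = data.labels.binary()
print(f"in-sample AUC {auc_score(y, p):.3f}, "
      f"MCC@0.5 {mcc_at_threshold(y, p, 0.5):.3f}")
# Positive weights on H3K27ac/H3K9ac/H2BK120ac and a negative weight on
# H3K27me3 recover the planted activating/repressive structure.
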