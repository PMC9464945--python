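"""Build the SPGIScore prognostic signature and evaluate it on held-out data.

The chain: pairwise differential expression among clusters -> genes recurrent
in >= 4 of the 6 pairwise comparisons -> univariate Cox screen (p < 0.05) ->
LASSO-Cox with 10-fold cross-validated penalty -> per-sample score, split at
the training median.
"""

import warnings

import numpy as np

import epmkit as ek

warnings.simplefilter("ignore")

net = ek.generate_network(300, 2, seed=1)
baseline = ek.gene_baseline(net, seed=1)
tumor, truth = ek.generate_tumor_cohort(net, baseline, 4, 75, 30, 1.0, 0.3, seed=3)
tumor = ek.plant_prognostic_genes(tumor, truth, n_prognostic=5, n_decoy=20, seed=4)
survival = ek.generate_survival(truth, tumor, censor_rate=0.3, seed=5)

lx = ek.log2p(tumor)
degs = ek.pairwise_degs(lx, truth.true_cluster)
recurrent = ek.recurrent_degs(degs, min_occurrences=4)
screen = ek.cox_screen(lx, survival, recurrent)
prognostic = sorted(screen.index[screen["prognostic"]])
print(f"{len(recurrent)} recurrent DEGs -> {len(prognostic)} prognostic (Cox p<0.05)")

model = ek.lasso_cox_fit(lx, survival, prognostic, n_folds=10, seed=6)
print(f"LASSO kept {len(model.genes)} genes at alpha = {model.alpha:.4f}:")
for g in model.genes:
    mark = " (planted)" if g in truth.prognostic_genes else ""
    print(f"  {g}: coef {model.coefficients[g]:+.3f}{mark}")

holdout, ho_truth = ek.generate_tumor_cohort(
    net, baseline, 4, 40, 30, 1.0, 0.3, seed=11,
    perturbed_edges=truth.perturbed_edges, prefix="H",
)
holdout = ek.plant_prognostic_genes(holdout, ho_truth, template=truth)
ho_surv = ek.generate_survival(ho_truth, holdout, censor_rate=0.3, seed=12)
scored = ek.spgi_score(model, ek.log2p(holdout))
report = ek.evaluate_prognosis(scored["score"], scored["high_risk"], ho_surv)
print(f"held-out: concordance {report['concordance']:.3f}, "
      f"log-rank p {report['logrank_p']:.2e}, "
      f"1y AUC {report['auc_1y'] and round(report['auc_1y'], 3)}")
print("-> a concordance well above 0.5 and a tiny log-rank p mean the score "
      "separates good from poor survival in unseen samples.")
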