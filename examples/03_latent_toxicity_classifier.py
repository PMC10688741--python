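"""Classify compound toxicity from the shared latent space.

Simulates a study where half the compounds carry a "toxic" expression
signature, trains one translation network per leave-one-compound-out fold,
and classifies each held-out compound from its latent embeddings with a
class-weighted linear SVM plus per-compound majority vote.

Run:  python examples/03_latent_toxicity_classifier.py   (~1 min)
"""

from toxtransfer import (
    LabelledCompoundSet,
    SimulationDesign,
    TrainingConfig,
    assign_toxicity_labels,
    build_learning_examples,
    classify_loocv,
    dataset_from_truth,
    draw_ground_truth,
    normalize_dataset,
    train_with_restarts,
)

design = SimulationDesign(n_compounds=6, gene_count=10,
                          domain_shift_magnitude=0.3, noise_sd=0.02, seed=5)
truth = draw_ground_truth(design)
labels, truth = assign_toxicity_labels(truth, 0.5, seed=5,
                                       perturbation_magnitude=0.3)
dataset = dataset_from_truth(truth, noise_seed=5)
labelled = LabelledCompoundSet("toxicity", labels)
print("labels:", ", ".join(f"{c}={l}" for c, l in sorted(labels.items())))

# One fold model per labelled compound, trained without that compound so its
# latent features are genuinely held out.
config = TrainingConfig(seed=5)
fold_models = {}
for held in labelled.compounds:
    train_compounds = [c for c in dataset.compounds if c != held]
    norm = normalize_dataset(dataset, fit_scope=train_compounds)
    source, target = build_learning_examples(norm.subset(train_compounds))
    model, _ = train_with_restarts(source, target, config,
                                   gene_set=dataset.gene_set,
                                   normalizer=norm.normalization)
    fold_models[held] = model
    print(f"fold model trained without {held}")

result = classify_loocv(dataset, labelled, fold_models)
print(f"\nvalidation accuracy: {result.validation_accuracy:.3f}")
print(f"sensitivity: {result.sensitivity:.3f}, "
      f"specificity: {result.specificity:.3f}")
print("confusion:", result.confusion)
for compound, call in sorted(result.predictions.items()):
    truth_label = labels[compound]
    mark = "ok" if call == truth_label else "MISS"
    print(f"  {compound}: predicted={call}  true={truth_label}  [{mark}]")
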