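"""Leave-one-compound-out evaluation and domain-mixing diagnostics.

Generalization to unseen chemicals is assessed with leave-one-compound-out
cross-validation (LOOCV): for each compound, all of its learning examples are
removed from both domains, normalization is refit on the remaining compounds,
the network is (re)trained, and the held-out source instances are scored. The
validation error of an instance is the mean absolute error between the
predicted and the measured in vivo time series, per gene, averaged over genes;
each instance is scored against its own paired in vivo replicate.

The with/without-adaptation comparison trains both arms on identical folds and
seeds and applies a two-tailed paired t-test to the instance-level errors.
Domain mixing in the learned representation is quantified two ways: PCA of the
per-layer embeddings (coordinates plus variance explained) and the held-out
accuracy of a freshly fitted linear probe classifying rat vs human from the
embeddings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from .data_model import (
    SOURCE,
    TARGET,
    ExposureDataset,
    LearningExample,
    build_learning_examples,
    normalize_dataset,
)
from .errors import DimensionMismatchError, DomainCompositionError
from .network import DANNModel, TrainingConfig, train_with_restarts


@dataclass
class InstanceRecord:
    """Scores for one held-out source instance in one fold."""

    compound: str
    dose: str
    vitro_replicate: int
    vivo_replicate: int
    per_gene_mae: np.ndarray
    instance_mae: float

    def key(self) -> tuple:
        return (self.compound, self.dose, self.vitro_replicate, self.vivo_replicate)


@dataclass
class FoldResult:
    """Outputs of one LOOCV fold: held-out scores, the model, embeddings."""

    held_out_compound: str
    instances: list[InstanceRecord]
    model: DANNModel
    collapse_report: dict
    heldout_latent: np.ndarray  # embeddings of held-out in vitro examples
    heldout_domains: np.ndarray  # 0 = rat (source), 1 = human (target)


@dataclass
class ComparisonResult:
    """Paired with/without-adaptation comparison of instance MAEs."""

    keys: list[tuple]
    mae_with: np.ndarray
    mae_without: np.ndarray
    mean_with: float
    sd_with: float
    mean_without: float
    sd_without: float
    t_statistic: float
    p_value: float
    degenerate: bool = False


def validation_error(
    predicted: np.ndarray, measured: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-gene and instance mean absolute error between genes x T matrices."""
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.shape != measured.shape:
        raise DimensionMismatchError(
            f"shape mismatch {predicted.shape} vs {measured.shape}"
        )
    if not (np.all(np.isfinite(predicted)) and np.all(np.isfinite(measured))):
        raise ValueError("non-finite values in validation inputs")
    per_gene = np.abs(predicted - measured).mean(axis=1)
    return per_gene, float(per_gene.mean())


def overall_mae(folds: list[FoldResult], pool_genes: bool = False) -> float:
    """Model score: unweighted mean of instance MAEs over all folds.

    ``pool_genes=True`` instead pools every gene x instance error equally;
    the two coincide when all instances share one gene set, as here, but the
    switch is kept explicit.
    """
    if pool_genes:
        errs = np.concatenate([r.per_gene_mae for f in folds for r in f.instances])
    else:
        errs = np.array([r.instance_mae for f in folds for r in f.instances])
    return float(errs.mean())


def _split_examples(
    examples: list[LearningExample], compound: str
) -> tuple[list[LearningExample], list[LearningExample]]:
    train = [e for e in examples if e.compound != compound]
    held = [e for e in examples if e.compound == compound]
    return train, held


def loocv(
    ds: ExposureDataset,
    config: TrainingConfig,
    max_restarts: int = 5,
    architecture=None,
    per_gene_norm: bool = True,
) -> list[FoldResult]:
    """One fold per compound: refit normalization, retrain, score held-out instances.

    ``ds`` is the raw (unnormalized) dataset; scaling is refit per fold on the
    training compounds only so that held-out compounds never leak into the
    normalization parameters. Deterministic given the config seed.
    """
    compounds = ds.compounds
    if len(compounds) < 2:
        raise ValueError("LOOCV needs at least two compounds")
    folds = []
    for compound in compounds:
        train_compounds = [c for c in compounds if c != compound]
        norm_ds = normalize_dataset(ds, fit_scope=train_compounds, per_gene=per_gene_norm)
        source, target = build_learning_examples(norm_ds)
        src_train, src_held = _split_examples(source, compound)
        tgt_train, tgt_held = _split_examples(target, compound)
        assert not any(e.compound == compound for e in src_train + tgt_train)
        model, report = train_with_restarts(
            src_train,
            tgt_train,
            config,
            max_restarts=max_restarts,
            architecture=architecture,
            gene_set=ds.gene_set,
            normalizer=norm_ds.normalization,
        )
        n_genes = len(ds.gene_set)
        records = []
        for ex in src_held:
            pred, _, _ = model.forward(ex.input_vector)
            per_gene, inst = validation_error(
                pred.reshape(n_genes, -1), ex.target_vector.reshape(n_genes, -1)
            )
            records.append(
                InstanceRecord(
                    compound=ex.compound,
                    dose=ex.dose,
                    vitro_replicate=ex.vitro_replicate,
                    vivo_replicate=ex.vivo_replicate,
                    per_gene_mae=per_gene,
                    instance_mae=inst,
                )
            )
        held_all = src_held + tgt_held
        X_held = np.array([e.input_vector for e in held_all])
        latent = model.latent_embedding(X_held)
        domains = np.array([0 if e.domain_label == SOURCE else 1 for e in held_all])
        folds.append(
            FoldResult(
                held_out_compound=compound,
                instances=records,
                model=model,
                collapse_report=report,
                heldout_latent=latent,
                heldout_domains=domains,
            )
        )
    return folds


def compare_with_without_da(
    ds: ExposureDataset,
    config: TrainingConfig,
    max_restarts: int = 5,
    architecture=None,
) -> tuple[ComparisonResult, list[FoldResult], list[FoldResult]]:
    """Run LOOCV with and without adaptation on identical folds and seeds.

    Instance MAEs are paired by (compound, dose, replicate pairing) and
    compared with a two-tailed paired t-test. When the paired differences are
    all exactly zero, t = 0 and p = 1; a zero-variance nonzero difference is
    flagged degenerate with NaN statistics.
    """
    cfg_with = replace(config, use_domain_adaptation=True)
    cfg_without = replace(config, use_domain_adaptation=False)
    folds_with = loocv(ds, cfg_with, max_restarts=max_restarts, architecture=architecture)
    folds_without = loocv(ds, cfg_without, max_restarts=max_restarts, architecture=architecture)
    by_key_with = {r.key(): r.instance_mae for f in folds_with for r in f.instances}
    by_key_without = {r.key(): r.instance_mae for f in folds_without for r in f.instances}
    if set(by_key_with) != set(by_key_without):
        raise ValueError("instance keys differ between the two comparison arms")
    keys = sorted(by_key_with)
    a = np.array([by_key_with[k] for k in keys])
    b = np.array([by_key_without[k] for k in keys])
    result = paired_comparison(keys, a, b)
    return result, folds_with, folds_without


def paired_comparison(keys, mae_with, mae_without) -> ComparisonResult:
    """Two-tailed paired t-test on instance-matched MAE pairs."""
    a = np.asarray(mae_with, dtype=float)
    b = np.asarray(mae_without, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired arrays must have equal length")
    diffs = a - b
    degenerate = False
    if np.allclose(diffs.std(ddof=1) if len(diffs) > 1 else 0.0, 0.0):
        if np.allclose(diffs, 0.0):
            t_stat, p_val = 0.0, 1.0
        else:
            warnings.warn("zero-variance nonzero paired differences", stacklevel=2)
            t_stat, p_val = float("nan"), float("nan")
            degenerate = True
    else:
        t_stat, p_val = stats.ttest_rel(a, b)
        t_stat, p_val = float(t_stat), float(p_val)
    return ComparisonResult(
        keys=list(keys),
        mae_with=a,
        mae_without=b,
        mean_with=float(a.mean()),
        sd_with=float(a.std(ddof=1)) if len(a) > 1 else 0.0,
        mean_without=float(b.mean()),
        sd_without=float(b.std(ddof=1)) if len(b) > 1 else 0.0,
        t_statistic=t_stat,
        p_value=p_val,
        degenerate=degenerate,
    )


def embedding_pca(
    model: DANNModel, examples: list[LearningExample], layer_index: int
) -> dict:
    """PCA of one layer's embeddings over the supplied in vitro examples.

    Centering without scaling (post-ReLU activations share a scale). Returns
    2-D coordinates, domain labels and the variance fraction of every
    component.
    """
    if len(examples) < 3:
        raise ValueError("need at least 3 examples for the PCA diagnostic")
    X = np.array([e.input_vector for e in examples])
    emb = model.forward(X)[2][layer_index]
    n_comp = min(emb.shape[0], emb.shape[1])
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(emb)
    return {
        "coordinates": coords[:, :2],
        "domains": np.array([0 if e.domain_label == SOURCE else 1 for e in examples]),
        "variance_fractions": pca.explained_variance_ratio_,
    }


def probe_accuracy(
    embeddings: np.ndarray, domains: np.ndarray, seed: int = 0, test_fraction: float = 0.5
) -> float:
    """Held-out accuracy of a fresh linear rat-vs-human probe on embeddings."""
    domains = np.asarray(domains)
    if len(np.unique(domains)) < 2:
        raise DomainCompositionError("probe needs examples from both domains")
    X_tr, X_te, y_tr, y_te = train_test_split(
        embeddings, domains, test_size=test_fraction, random_state=seed, stratify=domains
    )
    clf = LogisticRegression(max_iter=2000)
    clf.fit(X_tr, y_tr)
    return float(clf.score(X_te, y_te))


def domain_probe_accuracy(
    model: DANNModel,
    held_out_examples: list[LearningExample],
    layer_index: int | None = None,
    seed: int = 0,
) -> float:
    """Linear-probe rat-vs-human accuracy on a layer's embeddings of held-out examples.

    Chance level is the majority-class prior; values near chance indicate the
    layer no longer encodes the domain.
    """
    if layer_index is None:
        layer_index = model.architecture.latent_layer_index
    X = np.array([e.input_vector for e in held_out_examples])
    domains = np.array(
        [0 if e.domain_label == SOURCE else 1 for e in held_out_examples]
    )
    emb = model.forward(X)[2][layer_index]
    return probe_accuracy(emb, domains, seed=seed)
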