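"""Compound-toxicity classification from the network's latent space.

After adaptation, the bottleneck layer embeds rat and human in vitro exposure
responses in a shared low-dimensional space. A class-weighted linear SVM is
trained on those embeddings to call a binary toxicity label (for example
carcinogenicity or genotoxicity) per compound, under leave-one-compound-out
evaluation: each labelled compound is scored by the SVM fitted on the latent
features of the other labelled compounds, extracted from the fold model that
never saw the held-out compound. Control-dose exposures are excluded — they
carry no compound response. Record-level predictions for a compound are
aggregated to a single call by majority vote, with ties broken toward the
positive (toxic) class as the conservative call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .data_model import HUMAN_VITRO, RAT_VITRO, ExposureDataset, flatten_series
from .errors import NoLabelledCompoundsError, ToxTransferError
from .network import DANNModel

NON_CONTROL_DOSES = ("low", "medium", "high")


@dataclass
class LatentRecord:
    """One 64-dimensional latent embedding of an in vitro exposure instance."""

    compound: str
    dose: str
    domain: str
    replicate: int
    vector: np.ndarray


@dataclass
class LabelledCompoundSet:
    """Binary toxicity labels for the labelled subset of compounds."""

    label_name: str
    labels: dict[str, str]  # compound -> "positive" | "negative"

    def __post_init__(self):
        bad = {v for v in self.labels.values()} - {"positive", "negative"}
        if bad:
            raise ValueError(f"labels must be positive/negative, got {bad}")
        if not self.labels:
            raise NoLabelledCompoundsError("no labelled compounds")

    @property
    def compounds(self) -> tuple[str, ...]:
        return tuple(sorted(self.labels))


@dataclass
class LatentClassifierResult:
    """Record-level training accuracy plus compound-level validation metrics."""

    label_name: str
    training_accuracy: float
    validation_accuracy: float
    sensitivity: float
    specificity: float
    confusion: dict  # tp/fp/tn/fn counts at compound level
    predictions: dict  # compound -> predicted label
    skipped_folds: list


def extract_latent_features(
    model: DANNModel, ds: ExposureDataset, compounds
) -> list[LatentRecord]:
    """Latent embeddings of every non-control rat and human in vitro instance.

    One record per in vitro series (2 domains x 3 doses x replicates per
    compound). The dataset values are scaled with the model's stored
    normalization parameters before the forward pass, so records equal the
    embeddings the network itself computes.
    """
    known = set(ds.compounds)
    unknown = [c for c in compounds if c not in known]
    if unknown:
        raise ToxTransferError(f"unknown compounds: {unknown}")
    records: list[LatentRecord] = []
    for compound in sorted(compounds):
        for domain in (RAT_VITRO, HUMAN_VITRO):
            for dose in NON_CONTROL_DOSES:
                for series in ds.get(domain, compound, dose):
                    values = series.values
                    if model.normalizer is not None:
                        values = model.normalizer.transform(values)
                    vec = values.reshape(-1)
                    emb = model.latent_embedding(vec)
                    records.append(
                        LatentRecord(
                            compound=compound,
                            dose=dose,
                            domain=domain,
                            replicate=series.replicate,
                            vector=np.asarray(emb, dtype=float),
                        )
                    )
    if not records:
        warnings.warn("no non-control in vitro instances found", stacklevel=2)
    return records


def _fit_svm(X: np.ndarray, y: np.ndarray, C: float) -> SVC:
    # Class weights inversely proportional to class frequencies.
    clf = SVC(kernel="linear", C=C, class_weight="balanced")
    clf.fit(X, y)
    return clf


def classify_loocv(
    ds: ExposureDataset,
    labels: LabelledCompoundSet,
    fold_models: dict[str, DANNModel],
    C: float = 0.1,
) -> LatentClassifierResult:
    """Leave-one-compound-out toxicity classification in the latent space.

    For each labelled compound, the fold model trained without it supplies
    latent features for the remaining labelled compounds (SVM training set)
    and for the held-out compound (scored set). Folds whose training labels
    lack a class are skipped with a warning. The default C favors strong
    regularization: with tens of compounds the SVM sees few effective samples
    in a high-dimensional latent space and larger C over-fits compound
    identity. Training accuracy is reported at
    the record level; validation accuracy, sensitivity (positive = toxic) and
    specificity at the compound level.
    """
    labelled = labels.compounds
    missing = [c for c in labelled if c not in fold_models]
    if missing:
        raise ToxTransferError(f"no fold model for labelled compounds: {missing}")

    predictions: dict[str, str] = {}
    skipped: list[str] = []
    train_correct = 0
    train_total = 0
    for held in labelled:
        model = fold_models[held]
        train_compounds = [c for c in labelled if c != held]
        train_labels = {labels.labels[c] for c in train_compounds}
        if len(train_labels) < 2:
            warnings.warn(
                f"fold {held!r} skipped: training labels contain one class",
                stacklevel=2,
            )
            skipped.append(held)
            continue
        train_records = extract_latent_features(model, ds, train_compounds)
        assert all(r.compound != held for r in train_records)
        X = np.array([r.vector for r in train_records])
        y = np.array([1 if labels.labels[r.compound] == "positive" else 0 for r in train_records])
        clf = _fit_svm(X, y, C)
        train_correct += int((clf.predict(X) == y).sum())
        train_total += len(y)

        held_records = extract_latent_features(model, ds, [held])
        Xh = np.array([r.vector for r in held_records])
        calls = clf.predict(Xh)
        # Majority vote; ties break toward positive (toxic).
        positive = calls.sum() * 2 >= len(calls)
        predictions[held] = "positive" if positive else "negative"

    if not predictions:
        raise NoLabelledCompoundsError("every fold was skipped; no predictions made")

    tp = sum(
        1 for c, p in predictions.items() if p == "positive" and labels.labels[c] == "positive"
    )
    tn = sum(
        1 for c, p in predictions.items() if p == "negative" and labels.labels[c] == "negative"
    )
    fp = sum(
        1 for c, p in predictions.items() if p == "positive" and labels.labels[c] == "negative"
    )
    fn = sum(
        1 for c, p in predictions.items() if p == "negative" and labels.labels[c] == "positive"
    )
    n_scored = tp + tn + fp + fn
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return LatentClassifierResult(
        label_name=labels.label_name,
        training_accuracy=train_correct / train_total if train_total else float("nan"),
        validation_accuracy=(tp + tn) / n_scored,
        sensitivity=sens,
        specificity=spec,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        predictions=predictions,
        skipped_folds=skipped,
    )
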