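"""Domain-adversarial bottleneck network for in vitro -> in vivo translation.

The network maps a flattened in vitro time series (|genes| x 3 values) through
a bottleneck multilayer perceptron to a flattened in vivo prediction
(|genes| x 4 values, sigmoid-bounded). A small domain-classification arm reads
the latent (bottleneck) layer through a gradient reversal layer: identity in
the forward pass, multiplication of the backpropagated gradient by -lambda.
Training the arm to classify the input's domain (rat vs human in vitro) while
reversing its gradient into the shared layers drives the shared representation
toward domain invariance — unsupervised domain adaptation in the style of
Ganin et al.'s adversarial training.

Losses: the in vivo prediction error is the sum of absolute errors over source
(rat) examples; the domain error is softmax cross-entropy over all examples.
Target (human) examples carry no in vivo label and contribute to the domain
loss only. The reversal scale lambda follows the sigmoidal ramp
``2/(1+exp(-gamma*p)) - 1`` in training progress p, and the domain loss weight
ramps linearly from a floor to 1 over an initial warm-up fraction — placing
less weight on domain classification early in training, which reduces the
domain arm's tendency to collapse onto a single predicted class.

The parameter count is small (a few tens of thousands of weights), so forward
and reverse passes are written directly in NumPy; the hand-derived gradients
are validated against finite differences in the test suite.
"""

from __future__ import annotations

import copy
import hashlib
import json
import math
import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .data_model import (
    SOURCE,
    TARGET,
    VIVO_TIMES,
    ExposureSeries,
    GeneSet,
    LearningExample,
    Normalizer,
    flatten_series,
    unflatten_vector,
)
from .errors import (
    CheckpointError,
    DimensionMismatchError,
    DomainCompositionError,
    GeneSetMismatchError,
    InvalidScheduleInputError,
    TrainingDivergedError,
)

FLATTENING_CONVENTION = "gene-major"

#: Negative slope of the domain arm's leaky rectifier. A strictly rectified
#: arm can be permanently silenced by the adversarial trunk (all hidden units
#: pushed below zero kills every gradient, freezing the game with the domain
#: classifier predicting one class forever); a small negative slope keeps the
#: adversary trainable.
ARM_LEAK = 0.1


def lambda_schedule(progress: float, gamma: float = 10.0) -> float:
    """Reversal scale as a function of training progress p in [0, 1].

    ``2 / (1 + exp(-gamma * p)) - 1``: starts at exactly 0, saturates toward 1.
    """
    if not 0.0 <= progress <= 1.0:
        raise InvalidScheduleInputError(f"progress {progress} outside [0, 1]")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return 2.0 / (1.0 + math.exp(-gamma * progress)) - 1.0


def gradient_reversal(x: np.ndarray, lam: float) -> np.ndarray:
    """Forward pass of the gradient reversal layer: the identity.

    The layer's backward contract — the gradient of any downstream scalar with
    respect to ``x`` equals ``-lam`` times the gradient with respect to the
    layer output — is realized inside the network's backward pass and checked
    against finite differences in the tests.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return np.asarray(x)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer widths of the bottleneck network and its domain arm.

    ``latent_layer_index`` is a 0-based index into ``hidden_sizes`` addressing
    the bottleneck layer the domain arm reads (default: the third hidden
    layer, 64 units). ``domain_arm_sizes=None`` builds a network without a
    domain arm. With the defaults and a 76-gene set: input 228, latent 64,
    output 304.
    """

    input_dim: int
    output_dim: int
    hidden_sizes: tuple[int, ...] = (135, 90, 64, 120, 190)
    latent_layer_index: int = 2
    domain_arm_sizes: tuple[int, ...] | None = (8,)

    def __post_init__(self):
        object.__setattr__(self, "hidden_sizes", tuple(self.hidden_sizes))
        if self.domain_arm_sizes is not None:
            object.__setattr__(self, "domain_arm_sizes", tuple(self.domain_arm_sizes))
        if not 0 <= self.latent_layer_index < len(self.hidden_sizes):
            raise ValueError("latent_layer_index does not address a hidden layer")
        if self.input_dim < 1 or self.output_dim < 1:
            raise ValueError("input_dim and output_dim must be positive")

    @property
    def latent_width(self) -> int:
        return self.hidden_sizes[self.latent_layer_index]


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the momentum-SGD training loop.

    The optimizer settings are conventional defaults for a network of this
    size; all are exposed. ``domain_loss_warmup_fraction`` is the fraction of
    training over which the domain-loss weight ramps linearly from
    ``domain_weight_floor`` to 1.
    """

    learning_rate: float = 0.02
    momentum_coefficient: float = 0.9
    epochs: int = 400
    batch_size: int = 32
    lambda_gamma: float = 10.0
    domain_loss_warmup_fraction: float = 0.25
    domain_weight_floor: float = 0.1
    seed: int = 0
    use_domain_adaptation: bool = True
    collapse_threshold: float = 0.95
    collapse_window: int = 3
    # Adversary stabilization. The domain arm must stay close to its best
    # response as the shared representation moves — otherwise the trunk merely
    # hides domain information from a stale classifier (or silences it
    # outright) instead of removing the information. The arm therefore takes
    # several plain-SGD steps per trunk update, at a higher learning rate,
    # with L2 decay keeping its weights (and hence the reversed gradient)
    # bounded; the reversed gradient entering the trunk is additionally damped
    # to prevent the adversarial oscillation from diverging.
    arm_lr_multiplier: float = 10.0
    arm_steps: int = 5
    arm_weight_decay: float = 0.02
    adversary_gradient_scale: float = 0.5
    #: "single" runs the training loop in float32 (parameters are stored back
    #: as float64 afterwards); "double" keeps everything in float64. Single
    #: precision is ample for SGD on this scale and nearly halves wall time.
    precision: str = "single"

    def __post_init__(self):
        if self.precision not in ("single", "double"):
            raise ValueError("precision must be 'single' or 'double'")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 <= self.momentum_coefficient < 1:
            raise ValueError("momentum_coefficient must be in [0, 1)")
        if self.learning_rate <= 0 or self.lambda_gamma <= 0:
            raise ValueError("learning_rate and lambda_gamma must be positive")
        if not 0 <= self.domain_loss_warmup_fraction <= 1:
            raise ValueError("domain_loss_warmup_fraction must be in [0, 1]")


def _he_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _init_params(arch: ArchitectureSpec, seed: int) -> dict:
    """Seed-controlled He-style uniform initialization.

    The main path and the domain arm draw from independent seed streams so
    that the main-path initialization is identical whether or not the arm
    exists.
    """
    ss_main, ss_arm = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(ss_main)
    widths = [arch.input_dim, *arch.hidden_sizes, arch.output_dim]
    params = {"W": [], "b": [], "Wd": [], "bd": []}
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        params["W"].append(_he_uniform(rng, fan_in, fan_out))
        params["b"].append(np.zeros(fan_out))
    if arch.domain_arm_sizes is not None:
        rng_arm = np.random.default_rng(ss_arm)
        arm_widths = [arch.latent_width, *arch.domain_arm_sizes, 2]
        for fan_in, fan_out in zip(arm_widths[:-1], arm_widths[1:]):
            params["Wd"].append(_he_uniform(rng_arm, fan_in, fan_out))
            params["bd"].append(np.zeros(fan_out))
    return params


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))  # numerically stable logistic


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class DANNModel:
    """The bottleneck network plus everything needed to apply it to new data.

    Carries the architecture, weights, the gene set and normalization
    parameters it was trained with, the flattening convention, and the
    per-epoch training history.
    """

    def __init__(
        self,
        architecture: ArchitectureSpec,
        seed: int = 0,
        gene_set: GeneSet | None = None,
        normalizer: Normalizer | None = None,
        params: dict | None = None,
    ):
        self.architecture = architecture
        self.gene_set = gene_set
        self.normalizer = normalizer
        self.params = params if params is not None else _init_params(architecture, seed)
        self.training_history: dict[str, list] = {}
        self.training_config: TrainingConfig | None = None

    # -- forward ------------------------------------------------------------

    def _forward_cache(self, X: np.ndarray) -> dict:
        arch = self.architecture
        # Follow the parameter dtype so reduced-precision training stays pure.
        X = np.atleast_2d(np.asarray(X, dtype=self.params["W"][0].dtype))
        if X.shape[1] != arch.input_dim:
            raise DimensionMismatchError(
                f"input width {X.shape[1]} != architecture input_dim {arch.input_dim}"
            )
        hs, zs = [], []
        h = X
        n_hidden = len(arch.hidden_sizes)
        for i in range(n_hidden):
            z = h @ self.params["W"][i] + self.params["b"][i]
            h = np.maximum(z, 0.0)
            zs.append(z)
            hs.append(h)
        z_out = h @ self.params["W"][n_hidden] + self.params["b"][n_hidden]
        pred = _sigmoid(z_out)
        cache = {"X": X, "zs": zs, "hs": hs, "pred": pred}
        if arch.domain_arm_sizes is not None:
            latent = hs[arch.latent_layer_index]
            a = gradient_reversal(latent, 0.0)  # identity in the forward pass
            azs, ahs = [], []
            for i in range(len(arch.domain_arm_sizes)):
                az = a @ self.params["Wd"][i] + self.params["bd"][i]
                a = np.where(az > 0, az, ARM_LEAK * az)
                azs.append(az)
                ahs.append(a)
            logits = a @ self.params["Wd"][-1] + self.params["bd"][-1]
            cache.update({"arm_zs": azs, "arm_hs": ahs, "logits": logits})
        else:
            cache["logits"] = None
        return cache

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray | None, list[np.ndarray]]:
        """Return (in vivo prediction, domain logits, per-hidden-layer embeddings)."""
        single = np.asarray(X).ndim == 1
        cache = self._forward_cache(X)
        pred, logits, hs = cache["pred"], cache["logits"], cache["hs"]
        if single:
            pred = pred[0]
            hs = [h[0] for h in hs]
            logits = logits[0] if logits is not None else None
        return pred, logits, hs

    def latent_embedding(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[2][self.architecture.latent_layer_index]

    # -- arm-only passes (cheap: the trunk forward is reused) -----------------

    def _arm_forward(self, latent: np.ndarray) -> dict:
        a = latent
        azs, ahs = [], []
        for i in range(len(self.architecture.domain_arm_sizes)):
            az = a @ self.params["Wd"][i] + self.params["bd"][i]
            a = np.where(az > 0, az, ARM_LEAK * az)
            azs.append(az)
            ahs.append(a)
        logits = a @ self.params["Wd"][-1] + self.params["bd"][-1]
        return {"azs": azs, "ahs": ahs, "logits": logits}

    def _arm_backward(
        self, latent: np.ndarray, arm_cache: dict, y_dom: np.ndarray, scale: float
    ) -> tuple[dict, np.ndarray, float]:
        """Arm parameter grads, the (unreversed) gradient at the latent, and the CE sum."""
        n = latent.shape[0]
        p_soft = _softmax(arm_cache["logits"])
        ce_sum = float(-np.log(p_soft[np.arange(n), y_dom] + 1e-12).sum())
        d_logits = p_soft.copy()
        d_logits[np.arange(n), y_dom] -= 1.0
        d_logits *= scale
        n_arm = len(self.architecture.domain_arm_sizes)
        grads = {"Wd": [None] * (n_arm + 1), "bd": [None] * (n_arm + 1)}
        da = d_logits
        a_prev = arm_cache["ahs"][n_arm - 1] if n_arm > 0 else latent
        grads["Wd"][n_arm] = a_prev.T @ da
        grads["bd"][n_arm] = da.sum(axis=0)
        dh = da @ self.params["Wd"][n_arm].T
        for i in range(n_arm - 1, -1, -1):
            daz = dh * np.where(arm_cache["azs"][i] > 0, 1.0, ARM_LEAK)
            a_prev = arm_cache["ahs"][i - 1] if i > 0 else latent
            grads["Wd"][i] = a_prev.T @ daz
            grads["bd"][i] = daz.sum(axis=0)
            dh = daz @ self.params["Wd"][i].T
        return grads, dh, ce_sum

    # -- losses and gradients -------------------------------------------------

    def loss_and_grads(
        self,
        Xs: np.ndarray,
        Ys: np.ndarray,
        Xt: np.ndarray | None,
        lam: float,
        domain_weight: float = 1.0,
        adaptation: bool = True,
        pred_scale: float = 1.0,
        dom_scale: float = 1.0,
    ) -> tuple[dict, dict]:
        """Sum losses and their analytic gradients for one mixed batch.

        ``pred_scale``/``dom_scale`` multiply the respective gradient
        contributions (the training loop uses per-example means); the returned
        loss values are always unscaled sums, with ``domain_weight`` applied to
        the domain term. The gradient flowing from the domain arm into the
        shared layers is multiplied by ``-lam`` — the reversal contract.
        """
        arch = self.architecture
        Xs = np.atleast_2d(Xs)
        Ys = np.atleast_2d(Ys)
        ns = Xs.shape[0]
        use_arm = adaptation and arch.domain_arm_sizes is not None
        if use_arm and Xt is not None and len(Xt):
            Xt = np.atleast_2d(Xt)
            X = np.vstack([Xs, Xt])
            nt = Xt.shape[0]
        else:
            X = Xs
            nt = 0
        cache = self._forward_cache(X)
        pred = cache["pred"]
        n_hidden = len(arch.hidden_sizes)

        grads = {
            "W": [np.zeros_like(w) for w in self.params["W"]],
            "b": [np.zeros_like(b) for b in self.params["b"]],
            "Wd": [np.zeros_like(w) for w in self.params["Wd"]],
            "bd": [np.zeros_like(b) for b in self.params["bd"]],
        }

        # Prediction loss: sum of absolute errors over source rows only.
        resid = pred[:ns] - Ys
        pred_loss = float(np.abs(resid).sum())
        d_pred = np.zeros_like(pred)
        d_pred[:ns] = np.sign(resid) * pred_scale
        dz = d_pred * pred * (1.0 - pred)  # sigmoid derivative

        # Output layer back to (but excluding) the latent layer.
        h_prev = cache["hs"][n_hidden - 1]
        grads["W"][n_hidden] = h_prev.T @ dz
        grads["b"][n_hidden] = dz.sum(axis=0)
        dh = dz @ self.params["W"][n_hidden].T
        for i in range(n_hidden - 1, arch.latent_layer_index, -1):
            dz = dh * (cache["zs"][i] > 0)
            h_prev = cache["hs"][i - 1] if i > 0 else cache["X"]
            grads["W"][i] = h_prev.T @ dz
            grads["b"][i] = dz.sum(axis=0)
            dh = dz @ self.params["W"][i].T
        dh_latent = dh  # gradient at the latent activations from the main path

        # Domain arm: softmax cross-entropy over all rows, reversed into the trunk.
        domain_loss = 0.0
        if use_arm and cache["logits"] is not None:
            latent = cache["hs"][arch.latent_layer_index]
            y_dom = np.zeros(X.shape[0], dtype=int)
            y_dom[ns:] = 1  # 0 = source/rat, 1 = target/human
            arm_cache = {"azs": cache["arm_zs"], "ahs": cache["arm_hs"], "logits": cache["logits"]}
            arm_grads, dh_arm, ce_sum = self._arm_backward(
                latent, arm_cache, y_dom, scale=domain_weight * dom_scale
            )
            domain_loss = float(domain_weight * ce_sum)
            grads["Wd"] = arm_grads["Wd"]
            grads["bd"] = arm_grads["bd"]
            # Gradient reversal: the trunk receives -lambda times the arm gradient.
            dh_latent = dh_latent + (-lam) * dh_arm

        # Shared layers from the latent layer down to the input.
        dh = dh_latent
        for i in range(arch.latent_layer_index, -1, -1):
            dz = dh * (cache["zs"][i] > 0)
            h_prev = cache["hs"][i - 1] if i > 0 else cache["X"]
            grads["W"][i] = h_prev.T @ dz
            grads["b"][i] = dz.sum(axis=0)
            dh = dz @ self.params["W"][i].T

        losses = {
            "prediction": pred_loss,
            "domain": domain_loss,
            "total": pred_loss + domain_loss,
            "n_source": ns,
            "n_target": nt,
        }
        return losses, grads

    # -- application ----------------------------------------------------------

    def predict_in_vivo(
        self, vitro_series: ExposureSeries, denormalize: bool = False
    ) -> np.ndarray:
        """Predict the genes x 4 in vivo trajectory from an in vitro series.

        The input series is scaled with the model's stored normalization
        parameters; with ``denormalize=True`` the prediction is mapped back to
        the original expression scale.
        """
        if self.gene_set is not None and vitro_series.genes != self.gene_set.genes:
            raise GeneSetMismatchError(
                "series gene order does not match the model's gene set"
            )
        values = vitro_series.values
        if self.normalizer is not None:
            values = self.normalizer.transform(values)
        vec = values.reshape(-1)
        pred, _, _ = self.forward(vec)
        n_genes = values.shape[0]
        mat = unflatten_vector(pred, n_genes, len(VIVO_TIMES))
        if denormalize:
            if self.normalizer is None:
                raise ValueError("model has no stored normalization parameters")
            mat = self.normalizer.inverse_transform(mat)
        return mat

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        payload = {
            "format": "toxtransfer-checkpoint-v1",
            "flattening": FLATTENING_CONVENTION,
            "architecture": asdict(self.architecture),
            "gene_set": (
                {"name": self.gene_set.name, "genes": list(self.gene_set.genes)}
                if self.gene_set
                else None
            ),
            "normalizer": self.normalizer.to_dict() if self.normalizer else None,
            "training_config": asdict(self.training_config) if self.training_config else None,
            "params": {k: [a.tolist() for a in v] for k, v in self.params.items()},
        }
        body = json.dumps(payload, sort_keys=True)
        digest = hashlib.sha256(body.encode("utf-8")).hexdigest()
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump({"payload": payload, "sha256": digest}, fh)

    @classmethod
    def load(cls, path, expect_gene_set: GeneSet | None = None) -> "DANNModel":
        with open(path, "rt", encoding="utf-8") as fh:
            blob = json.load(fh)
        payload = blob.get("payload")
        body = json.dumps(payload, sort_keys=True)
        if hashlib.sha256(body.encode("utf-8")).hexdigest() != blob.get("sha256"):
            raise CheckpointError(f"checkpoint {path} failed its content hash")
        arch_d = dict(payload["architecture"])
        arch_d["hidden_sizes"] = tuple(arch_d["hidden_sizes"])
        if arch_d.get("domain_arm_sizes") is not None:
            arch_d["domain_arm_sizes"] = tuple(arch_d["domain_arm_sizes"])
        arch = ArchitectureSpec(**arch_d)
        gene_set = None
        if payload["gene_set"] is not None:
            gene_set = GeneSet(payload["gene_set"]["name"], tuple(payload["gene_set"]["genes"]))
        if expect_gene_set is not None:
            if gene_set is None or gene_set.genes != expect_gene_set.genes:
                raise GeneSetMismatchError(
                    "checkpoint gene set does not match the expected gene set"
                )
        normalizer = (
            Normalizer.from_dict(payload["normalizer"]) if payload["normalizer"] else None
        )
        params = {
            k: [np.asarray(a, dtype=float) for a in v]
            for k, v in payload["params"].items()
        }
        model = cls(arch, gene_set=gene_set, normalizer=normalizer, params=params)
        if payload.get("training_config"):
            model.training_config = TrainingConfig(**payload["training_config"])
        return model


def compute_losses(
    batch: list[LearningExample],
    model: DANNModel,
    lam: float,
    domain_weight: float = 1.0,
    use_domain_adaptation: bool = True,
) -> tuple[float, float, float]:
    """Sum prediction and domain losses over a batch of learning examples.

    Prediction loss: sum over source examples of the sum of absolute errors
    (target examples contribute zero). Domain loss: softmax cross-entropy of
    the domain logits against the domain labels over all examples, scaled by
    ``domain_weight``. With adaptation off the total equals the prediction
    loss exactly.
    """
    if not batch:
        raise ValueError("batch must be non-empty")
    src = [e for e in batch if e.domain_label == SOURCE]
    tgt = [e for e in batch if e.domain_label == TARGET]
    if not use_domain_adaptation and not src:
        raise DomainCompositionError(
            "batch contains only target examples but domain adaptation is off"
        )
    Xs = np.array([e.input_vector for e in src]) if src else np.zeros((0, model.architecture.input_dim))
    Ys = np.array([e.target_vector for e in src]) if src else np.zeros((0, model.architecture.output_dim))
    Xt = np.array([e.input_vector for e in tgt]) if tgt else None

    pred_loss = 0.0
    if src:
        pred, _, _ = model.forward(Xs)
        pred_loss = float(np.abs(np.atleast_2d(pred) - Ys).sum())
    domain_loss = 0.0
    if use_domain_adaptation and model.architecture.domain_arm_sizes is not None:
        X_all = np.vstack([m for m in (Xs, Xt) if m is not None and len(m)])
        y_dom = np.array([0] * len(src) + [1] * len(tgt))
        _, logits, _ = model.forward(X_all)
        p_soft = _softmax(np.atleast_2d(logits))
        ce = -np.log(p_soft[np.arange(len(y_dom)), y_dom] + 1e-12)
        domain_loss = float(domain_weight * ce.sum())
    total = pred_loss + domain_loss
    return pred_loss, domain_loss, total


def _domain_weight(progress: float, config: TrainingConfig) -> float:
    w = config.domain_loss_warmup_fraction
    if w <= 0 or progress >= w:
        return 1.0
    floor = config.domain_weight_floor
    return floor + (1.0 - floor) * (progress / w)


def train(
    examples_source: list[LearningExample],
    examples_target: list[LearningExample],
    config: TrainingConfig,
    architecture: ArchitectureSpec | None = None,
    gene_set: GeneSet | None = None,
    normalizer: Normalizer | None = None,
) -> DANNModel:
    """Train the network with momentum SGD over shuffled mixed batches.

    Source batches are drawn from a seed stream that does not depend on the
    target examples, so a run with ``use_domain_adaptation=False`` (which
    excludes target examples and gives the domain arm no gradient) follows
    exactly the same source-batch sequence as an adaptation run — the two
    differ only in the adversarial term. Fully reproducible from the seed.
    """
    if not examples_source:
        raise ValueError("no source examples")
    for e in examples_source:
        if e.target_vector is None:
            raise ValueError("source examples must carry target vectors")
    Xs = np.array([e.input_vector for e in examples_source])
    Ys = np.array([e.target_vector for e in examples_source])
    adaptation = config.use_domain_adaptation
    Xt = (
        np.array([e.input_vector for e in examples_target])
        if (adaptation and examples_target)
        else None
    )
    if architecture is None:
        arm = (8,) if adaptation else None
        architecture = ArchitectureSpec(
            input_dim=Xs.shape[1], output_dim=Ys.shape[1], domain_arm_sizes=arm
        )

    ss = np.random.SeedSequence(config.seed)
    _, _, ss_src, ss_tgt = ss.spawn(4)
    model = DANNModel(architecture, seed=config.seed, gene_set=gene_set, normalizer=normalizer)
    model.training_config = config
    rng_src = np.random.default_rng(ss_src)
    rng_tgt = np.random.default_rng(ss_tgt)

    dtype = np.float32 if config.precision == "single" else np.float64
    Xs = Xs.astype(dtype)
    Ys = Ys.astype(dtype)
    if Xt is not None:
        Xt = Xt.astype(dtype)
    for k in model.params:
        model.params[k] = [a.astype(dtype) for a in model.params[k]]

    ns = Xs.shape[0]
    nt = Xt.shape[0] if Xt is not None else 0
    batch = min(config.batch_size, ns)
    n_batches = math.ceil(ns / batch)
    total_steps = config.epochs * n_batches

    velocity = {k: [np.zeros_like(a) for a in v] for k, v in model.params.items()}
    history: dict[str, list] = {
        "prediction_loss": [],
        "domain_loss": [],
        "domain_majority_fraction": [],
        "domain_human_fraction": [],
        "lambda": [],
        "domain_weight": [],
    }
    model.training_history = history

    step = 0
    mu, lr = config.momentum_coefficient, config.learning_rate
    for epoch in range(config.epochs):
        perm_s = rng_src.permutation(ns)
        if adaptation and nt:
            perm_t = rng_tgt.permutation(nt)
            # Cycle target indices so every source batch gets a target batch.
            tgt_seq = np.resize(perm_t, ns)
        for b in range(n_batches):
            progress = step / max(total_steps - 1, 1)
            lam = lambda_schedule(progress, config.lambda_gamma) if adaptation else 0.0
            dw = _domain_weight(progress, config) if adaptation else 0.0
            idx = perm_s[b * batch : (b + 1) * batch]
            xb, yb = Xs[idx], Ys[idx]
            use_arm = (
                adaptation and nt > 0 and architecture.domain_arm_sizes is not None
            )
            if use_arm:
                tidx = tgt_seq[b * batch : (b + 1) * batch]
                xt = Xt[tidx]
                n_all = len(idx) + len(xt)
                X_all = np.vstack([xb, xt])
                y_dom = np.zeros(n_all, dtype=int)
                y_dom[len(idx):] = 1
            else:
                X_all = xb
                n_all = len(idx)

            cache = model._forward_cache(X_all)
            pred = cache["pred"]
            n_hidden = len(architecture.hidden_sizes)
            latent_idx = architecture.latent_layer_index
            latent = cache["hs"][latent_idx]

            if use_arm:
                # Critic phase: bring the arm near its best response to the
                # current (fixed) latent representation.
                arm_lr = lr * config.arm_lr_multiplier
                for _ in range(config.arm_steps):
                    arm_cache = model._arm_forward(latent)
                    arm_grads, _, _ = model._arm_backward(
                        latent, arm_cache, y_dom, scale=1.0 / n_all
                    )
                    for i in range(len(model.params["Wd"])):
                        model.params["Wd"][i] -= arm_lr * (
                            arm_grads["Wd"][i]
                            + config.arm_weight_decay * model.params["Wd"][i]
                        )
                        model.params["bd"][i] -= arm_lr * arm_grads["bd"][i]

            # Trunk phase: prediction gradient (per-dimension mean scale) plus
            # the damped, reversed domain gradient from the refreshed arm.
            ns_b = len(idx)
            resid = pred[:ns_b] - yb
            pred_loss = float(np.abs(resid).sum())
            d_pred = np.zeros_like(pred)
            d_pred[:ns_b] = np.sign(resid) / (ns_b * architecture.output_dim)
            dz = d_pred * pred * (1.0 - pred)
            grads_W = [None] * (n_hidden + 1)
            grads_b = [None] * (n_hidden + 1)
            h_prev = cache["hs"][n_hidden - 1]
            grads_W[n_hidden] = h_prev.T @ dz
            grads_b[n_hidden] = dz.sum(axis=0)
            dh = dz @ model.params["W"][n_hidden].T
            for i in range(n_hidden - 1, latent_idx, -1):
                dz = dh * (cache["zs"][i] > 0)
                h_prev = cache["hs"][i - 1] if i > 0 else cache["X"]
                grads_W[i] = h_prev.T @ dz
                grads_b[i] = dz.sum(axis=0)
                dh = dz @ model.params["W"][i].T
            domain_loss = 0.0
            if use_arm:
                arm_cache = model._arm_forward(latent)
                _, dh_arm, ce_sum = model._arm_backward(
                    latent, arm_cache, y_dom, scale=1.0 / n_all
                )
                domain_loss = dw * ce_sum
                dh = dh + (-lam * dw * config.adversary_gradient_scale) * dh_arm
            for i in range(latent_idx, -1, -1):
                dz = dh * (cache["zs"][i] > 0)
                h_prev = cache["hs"][i - 1] if i > 0 else cache["X"]
                grads_W[i] = h_prev.T @ dz
                grads_b[i] = dz.sum(axis=0)
                dh = dz @ model.params["W"][i].T

            if not np.isfinite(pred_loss + domain_loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, step {step}", history=history
                )
            for i in range(len(model.params["W"])):
                velocity["W"][i] = mu * velocity["W"][i] - lr * grads_W[i]
                model.params["W"][i] = model.params["W"][i] + velocity["W"][i]
                velocity["b"][i] = mu * velocity["b"][i] - lr * grads_b[i]
                model.params["b"][i] = model.params["b"][i] + velocity["b"][i]
            step += 1

        # Per-epoch bookkeeping on the full data (one forward pass serves both
        # the prediction loss and the domain-class balance).
        if adaptation and Xt is not None and architecture.domain_arm_sizes is not None:
            cache_full = model._forward_cache(np.vstack([Xs, Xt]))
            pred_full = cache_full["pred"][:ns]
            logits_full = cache_full["logits"]
        else:
            cache_full = model._forward_cache(Xs)
            pred_full = cache_full["pred"]
            logits_full = None
        pred_loss_full = float(np.abs(pred_full - Ys).sum())
        history["prediction_loss"].append(pred_loss_full)
        history["lambda"].append(lam)
        history["domain_weight"].append(dw if adaptation else 0.0)
        if logits_full is not None:
            p_soft = _softmax(logits_full)
            y_dom = np.array([0] * ns + [1] * nt)
            ce = float(-np.log(p_soft[np.arange(ns + nt), y_dom] + 1e-12).sum())
            calls = p_soft.argmax(axis=1)
            human_frac = float((calls == 1).mean())
            majority = max(human_frac, 1.0 - human_frac)
            history["domain_loss"].append(ce)
            history["domain_majority_fraction"].append(majority)
            history["domain_human_fraction"].append(human_frac)
        else:
            history["domain_loss"].append(float("nan"))
            history["domain_majority_fraction"].append(float("nan"))
            history["domain_human_fraction"].append(float("nan"))
        if not np.isfinite(pred_loss_full):
            raise TrainingDivergedError(
                f"non-finite epoch loss at epoch {epoch}", history=history
            )
    for k in model.params:
        model.params[k] = [a.astype(np.float64) for a in model.params[k]]
    return model


def detect_mode_collapse(
    history_window: list[float] | np.ndarray,
    threshold: float = 0.95,
    human_fractions: list[float] | None = None,
) -> bool:
    """True iff one domain class dominates beyond ``threshold`` in every epoch.

    ``history_window`` holds the per-epoch fraction of examples assigned to
    the majority domain class. When ``human_fractions`` is given, the
    dominating class must also be the same across the window.
    """
    window = np.asarray(list(history_window), dtype=float)
    if window.size == 0 or np.any(~np.isfinite(window)):
        return False
    if not np.all(window > threshold):
        return False
    if human_fractions is not None:
        hf = np.asarray(list(human_fractions), dtype=float)
        same_class = np.all(hf > 0.5) or np.all(hf < 0.5)
        return bool(same_class)
    return True


def model_collapsed(model: DANNModel, config: TrainingConfig) -> bool:
    """Apply the collapse detector to the tail of a model's training history."""
    hist = model.training_history
    w = config.collapse_window
    if not hist or len(hist.get("domain_majority_fraction", [])) < w:
        return False
    return detect_mode_collapse(
        hist["domain_majority_fraction"][-w:],
        threshold=config.collapse_threshold,
        human_fractions=hist["domain_human_fraction"][-w:],
    )


def train_with_restarts(
    examples_source: list[LearningExample],
    examples_target: list[LearningExample],
    config: TrainingConfig,
    max_restarts: int = 5,
    architecture: ArchitectureSpec | None = None,
    gene_set: GeneSet | None = None,
    normalizer: Normalizer | None = None,
) -> tuple[DANNModel, dict]:
    """Retrain with incremented seeds until the domain arm has not collapsed.

    Returns the model plus a collapse report. If every attempt collapsed, the
    model with the lowest final prediction loss is returned, flagged.
    """
    if max_restarts < 0:
        raise ValueError("max_restarts must be >= 0")
    attempts = []
    best = None
    for attempt in range(max_restarts + 1):
        cfg = replace(config, seed=config.seed + attempt)
        model = train(
            examples_source,
            examples_target,
            cfg,
            architecture=architecture,
            gene_set=gene_set,
            normalizer=normalizer,
        )
        collapsed = config.use_domain_adaptation and model_collapsed(model, cfg)
        final_loss = model.training_history["prediction_loss"][-1]
        attempts.append({"seed": cfg.seed, "collapsed": collapsed, "final_prediction_loss": final_loss})
        if best is None or final_loss < best[1]:
            best = (model, final_loss)
        if not collapsed:
            report = {"collapsed": False, "runs": attempt + 1, "attempts": attempts}
            return model, report
    warnings.warn(
        f"domain classifier collapsed in all {max_restarts + 1} run(s); "
        "returning the best model by prediction loss",
        stacklevel=2,
    )
    return best[0], {"collapsed": True, "runs": len(attempts), "attempts": attempts}
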