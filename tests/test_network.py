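"""Network core: schedule, gradient reversal (finite differences), losses,
training loop, collapse guard, restarts and checkpointing."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import toxtransfer.network as net
from toxtransfer import (
    ArchitectureSpec,
    DANNModel,
    GeneSet,
    TrainingConfig,
    build_learning_examples,
    compute_losses,
    detect_mode_collapse,
    gradient_reversal,
    lambda_schedule,
    normalize_dataset,
    simulate_dataset,
    train,
    train_with_restarts,
)
from toxtransfer.data_model import SOURCE, TARGET, LearningExample
from toxtransfer.errors import (
    CheckpointError,
    DimensionMismatchError,
    DomainCompositionError,
    GeneSetMismatchError,
    InvalidScheduleInputError,
    TrainingDivergedError,
)
from toxtransfer.simulate import SimulationDesign


# -- lambda schedule -------------------------------------------------------------


def test_schedule_starts_at_zero():
    assert lambda_schedule(0.0) == 0.0


def test_schedule_closed_form_midpoint():
    expected = 2.0 / (1.0 + math.exp(-5.0)) - 1.0
    assert lambda_schedule(0.5, gamma=10.0) == pytest.approx(expected, abs=1e-9)


def test_schedule_saturates_toward_one():
    assert lambda_schedule(1.0, gamma=200.0) == pytest.approx(1.0, abs=1e-12)
    assert lambda_schedule(1.0, gamma=10.0) < 1.0


def test_schedule_monotone_on_grid():
    grid = np.linspace(0.0, 1.0, 1000)
    vals = [lambda_schedule(p, gamma=10.0) for p in grid]
    assert all(b >= a for a, b in zip(vals, vals[1:]))


def test_schedule_rejects_out_of_range_progress():
    with pytest.raises(InvalidScheduleInputError):
        lambda_schedule(-0.01)
    with pytest.raises(InvalidScheduleInputError):
        lambda_schedule(1.01)
    with pytest.raises(ValueError):
        lambda_schedule(0.5, gamma=0.0)


@given(st.floats(min_value=0.0, max_value=1.0))
def test_schedule_range_property(p):
    v = lambda_schedule(p, gamma=10.0)
    assert 0.0 <= v < 1.0


# -- gradient reversal: identity forward + finite-difference contract -------------


def test_reversal_forward_is_identity(rng):
    x = rng.normal(size=12)
    for lam in (0.0, 0.3, 1.0):
        assert np.array_equal(gradient_reversal(x, lam), x)
    with pytest.raises(ValueError):
        gradient_reversal(x, -0.1)


def _toy_model_and_batch(seed=0, n_src=4, n_tgt=3):
    """5-dim toy network with a domain arm, plus a mixed batch."""
    arch = ArchitectureSpec(
        input_dim=5, output_dim=4, hidden_sizes=(6, 5, 4),
        latent_layer_index=1, domain_arm_sizes=(3,),
    )
    model = DANNModel(arch, seed=seed)
    rng = np.random.default_rng(seed + 100)
    Xs = rng.uniform(0.1, 0.9, size=(n_src, 5))
    Ys = rng.uniform(0.1, 0.9, size=(n_src, 4))
    Xt = rng.uniform(0.1, 0.9, size=(n_tgt, 5))
    return model, Xs, Ys, Xt


def _fd_grad(model, Xs, Ys, Xt, which, layer, index, loss_key, eps=1e-6):
    """Central finite difference of one loss component w.r.t. one parameter."""
    p = model.params[which][layer]
    orig = p.flat[index]
    p.flat[index] = orig + eps
    up, _ = model.loss_and_grads(Xs, Ys, Xt, lam=0.0)
    p.flat[index] = orig - eps
    dn, _ = model.loss_and_grads(Xs, Ys, Xt, lam=0.0)
    p.flat[index] = orig
    return (up[loss_key] - dn[loss_key]) / (2 * eps)


@pytest.mark.parametrize("lam", [0.0, 0.3, 1.0])
def test_reversal_contract_by_finite_differences(lam):
    """Shared-layer gradients change by exactly -lam x (FD of the domain loss)."""
    model, Xs, Ys, Xt = _toy_model_and_batch()
    _, g_lam = model.loss_and_grads(Xs, Ys, Xt, lam=lam)
    _, g_zero = model.loss_and_grads(Xs, Ys, Xt, lam=0.0)
    rng = np.random.default_rng(7)
    checked = 0
    for layer in range(len(model.params["W"])):
        size = model.params["W"][layer].size
        for index in rng.choice(size, size=min(6, size), replace=False):
            analytic = g_lam["W"][layer].flat[index] - g_zero["W"][layer].flat[index]
            fd_dom = _fd_grad(model, Xs, Ys, Xt, "W", layer, index, "domain")
            expected = -lam * fd_dom
            assert analytic == pytest.approx(expected, rel=1e-4, abs=1e-9)
            checked += 1
    assert checked >= 20


def test_prediction_and_arm_gradients_match_finite_differences():
    model, Xs, Ys, Xt = _toy_model_and_batch(seed=3)
    _, grads = model.loss_and_grads(Xs, Ys, Xt, lam=0.0)
    rng = np.random.default_rng(11)
    # Shared weights against the prediction loss (lam = 0 removes the arm path).
    for layer in range(len(model.params["W"])):
        size = model.params["W"][layer].size
        for index in rng.choice(size, size=min(5, size), replace=False):
            fd = _fd_grad(model, Xs, Ys, Xt, "W", layer, index, "prediction")
            assert grads["W"][layer].flat[index] == pytest.approx(fd, rel=2e-3, abs=1e-7)
    # Arm weights against the domain loss (positive sign: the arm minimizes CE).
    for layer in range(len(model.params["Wd"])):
        size = model.params["Wd"][layer].size
        for index in rng.choice(size, size=min(5, size), replace=False):
            fd = _fd_grad(model, Xs, Ys, Xt, "Wd", layer, index, "domain")
            assert grads["Wd"][layer].flat[index] == pytest.approx(fd, rel=1e-4, abs=1e-9)


# -- forward pass ------------------------------------------------------------------


def test_zero_weights_predict_half_everywhere():
    arch = ArchitectureSpec(input_dim=6, output_dim=8, hidden_sizes=(5, 4, 3),
                            latent_layer_index=1)
    model = DANNModel(arch)
    for k in ("W", "b", "Wd", "bd"):
        model.params[k] = [np.zeros_like(a) for a in model.params[k]]
    pred, logits, _ = model.forward(np.linspace(0, 1, 6))
    assert np.all(pred == 0.5)
    assert np.all(logits == 0.0)


def test_forward_widths_for_76_gene_model():
    arch = ArchitectureSpec(input_dim=228, output_dim=304)
    model = DANNModel(arch, seed=1)
    pred, logits, embeddings = model.forward(np.full(228, 0.4))
    assert [e.shape[-1] for e in embeddings] == [135, 90, 64, 120, 190]
    assert pred.shape == (304,)
    assert logits.shape == (2,)
    assert model.architecture.latent_width == 64
    assert np.all((pred > 0) & (pred < 1))  # sigmoid head, no clipping


def test_forward_rejects_wrong_input_width():
    model = DANNModel(ArchitectureSpec(input_dim=6, output_dim=4,
                                       hidden_sizes=(5, 4, 3), latent_layer_index=1))
    with pytest.raises(DimensionMismatchError):
        model.forward(np.zeros(7))


def test_forward_deterministic_across_identical_models():
    a = DANNModel(ArchitectureSpec(input_dim=5, output_dim=4,
                                   hidden_sizes=(6, 5, 4), latent_layer_index=1), seed=9)
    b = DANNModel(ArchitectureSpec(input_dim=5, output_dim=4,
                                   hidden_sizes=(6, 5, 4), latent_layer_index=1), seed=9)
    x = np.linspace(0.1, 0.9, 5)
    assert np.array_equal(a.forward(x)[0], b.forward(x)[0])


# -- losses -------------------------------------------------------------------------


def _example(domain_label, x, y=None, compound="c1", dose="low"):
    return LearningExample(domain_label=domain_label, compound=compound, dose=dose,
                           vitro_replicate=1, vivo_replicate=1 if y is not None else None,
                           input_vector=np.asarray(x, dtype=float),
                           target_vector=None if y is None else np.asarray(y, dtype=float))


def test_perfect_fit_gives_zero_prediction_loss():
    model, Xs, _, _ = _toy_model_and_batch()
    x = Xs[0]
    pred, _, _ = model.forward(x)
    batch = [_example(SOURCE, x, pred)]
    pred_loss, _, _ = compute_losses(batch, model, lam=0.0)
    assert pred_loss == pytest.approx(0.0, abs=1e-12)


def test_losses_match_hand_computation():
    """2-gene toy: sum |diff| and softmax cross-entropy computed by hand."""
    arch = ArchitectureSpec(input_dim=6, output_dim=8, hidden_sizes=(4, 3),
                            latent_layer_index=1, domain_arm_sizes=(2,))
    model = DANNModel(arch, seed=5)
    x_s = np.linspace(0.2, 0.8, 6)
    x_t = np.linspace(0.9, 0.3, 6)
    y = np.full(8, 0.4)
    pred, logit_s, _ = model.forward(x_s)
    _, logit_t, _ = model.forward(x_t)
    expected_pred = float(np.abs(pred - y).sum())

    def ce(logits, label):
        e = np.exp(logits - logits.max())
        p = e / e.sum()
        return -math.log(p[label] + 1e-12)

    expected_dom = ce(logit_s, 0) + ce(logit_t, 1)
    w = 0.7
    pl, dl, total = compute_losses(
        [_example(SOURCE, x_s, y), _example(TARGET, x_t)],
        model, lam=0.5, domain_weight=w,
    )
    assert pl == pytest.approx(expected_pred, rel=1e-12)
    assert dl == pytest.approx(w * expected_dom, rel=1e-9)
    assert total == pytest.approx(pl + dl, rel=1e-12)


def test_uniform_logits_give_batchsize_ln2():
    arch = ArchitectureSpec(input_dim=4, output_dim=4, hidden_sizes=(3, 2),
                            latent_layer_index=1, domain_arm_sizes=(2,))
    model = DANNModel(arch, seed=0)
    for k in ("Wd", "bd"):
        model.params[k] = [np.zeros_like(a) for a in model.params[k]]
    batch = []
    rng = np.random.default_rng(0)
    for _ in range(4):
        batch.append(_example(SOURCE, rng.uniform(0, 1, 4), rng.uniform(0, 1, 4)))
        batch.append(_example(TARGET, rng.uniform(0, 1, 4)))
    w = 0.6
    _, dl, _ = compute_losses(batch, model, lam=0.2, domain_weight=w)
    assert dl == pytest.approx(8 * math.log(2.0) * w, rel=1e-9)


def test_adaptation_off_total_equals_prediction_loss():
    model, Xs, Ys, _ = _toy_model_and_batch()
    batch = [_example(SOURCE, x, y) for x, y in zip(Xs, Ys)]
    pl, dl, total = compute_losses(batch, model, lam=0.9,
                                   use_domain_adaptation=False)
    assert dl == 0.0
    assert total == pl


def test_target_only_batch_with_adaptation_off_raises():
    model, Xs, _, _ = _toy_model_and_batch()
    with pytest.raises(DomainCompositionError):
        compute_losses([_example(TARGET, Xs[0])], model, lam=0.0,
                       use_domain_adaptation=False)


# -- training loop -------------------------------------------------------------------


def _small_problem(seed, n_compounds=5, adaptation=True, epochs=40):
    design = SimulationDesign(n_compounds=n_compounds, gene_count=5,
                              noise_sd=0.01, domain_shift_magnitude=0.3, seed=seed)
    ds, _ = simulate_dataset(design)
    norm = normalize_dataset(ds, fit_scope=ds.compounds)
    source, target = build_learning_examples(norm)
    cfg = TrainingConfig(epochs=epochs, batch_size=32, seed=seed,
                         use_domain_adaptation=adaptation)
    return source, target, cfg


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_training_reduces_prediction_loss(seed):
    source, target, cfg = _small_problem(seed)
    model = train(source, target, cfg)
    hist = model.training_history["prediction_loss"]
    assert hist[-1] < hist[0]


def test_adaptation_off_equals_arm_free_network():
    source, target, cfg = _small_problem(6, epochs=8)
    cfg_off = TrainingConfig(**{**cfg.__dict__, "use_domain_adaptation": False})
    g = 5
    arch_arm = ArchitectureSpec(input_dim=3 * g, output_dim=4 * g,
                                hidden_sizes=(8, 6, 5), latent_layer_index=1,
                                domain_arm_sizes=(3,))
    arch_free = ArchitectureSpec(input_dim=3 * g, output_dim=4 * g,
                                 hidden_sizes=(8, 6, 5), latent_layer_index=1,
                                 domain_arm_sizes=None)
    m_off = train(source, target, cfg_off, architecture=arch_arm)
    m_free = train(source, [], cfg_off, architecture=arch_free)
    for a, b in zip(m_off.params["W"], m_free.params["W"]):
        assert np.array_equal(a, b)
    for a, b in zip(m_off.params["b"], m_free.params["b"]):
        assert np.array_equal(a, b)


def test_lambda_forced_to_zero_matches_adaptation_off_trunk(monkeypatch):
    # Double precision: with lam = 0 the trunk updates are mathematically
    # identical, but single-precision GEMM rounds the shared rows differently
    # when the batch matrix carries extra target rows.
    source, target, cfg = _small_problem(8, epochs=6)
    cfg = TrainingConfig(**{**cfg.__dict__, "precision": "double"})
    cfg_off = TrainingConfig(**{**cfg.__dict__, "use_domain_adaptation": False})
    g = 5
    arch = ArchitectureSpec(input_dim=3 * g, output_dim=4 * g,
                            hidden_sizes=(8, 6, 5), latent_layer_index=1,
                            domain_arm_sizes=(3,))
    m_off = train(source, target, cfg_off, architecture=arch)
    monkeypatch.setattr(net, "lambda_schedule", lambda p, gamma=10.0: 0.0)
    m_zero = train(source, target, cfg, architecture=arch)
    for a, b in zip(m_zero.params["W"], m_off.params["W"]):
        assert np.array_equal(a, b)  # trunk identical; arm weights may differ


def test_training_is_bit_reproducible():
    source, target, cfg = _small_problem(9, epochs=5)
    m1 = train(source, target, cfg)
    m2 = train(source, target, cfg)
    for k in ("W", "b", "Wd", "bd"):
        for a, b in zip(m1.params[k], m2.params[k]):
            assert np.array_equal(a, b)
    m3 = train(source, target, TrainingConfig(**{**cfg.__dict__, "seed": cfg.seed + 1}))
    assert any(not np.array_equal(a, b)
               for a, b in zip(m1.params["W"], m3.params["W"]))


@pytest.mark.filterwarnings("ignore::RuntimeWarning")
def test_divergence_raises_named_error_with_history():
    source, target, cfg = _small_problem(10, epochs=10)
    bad = TrainingConfig(**{**cfg.__dict__, "learning_rate": 1e9})
    with pytest.raises(TrainingDivergedError) as exc:
        train(source, target, bad)
    assert isinstance(exc.value.history, dict)


def test_source_examples_must_carry_targets():
    source, target, cfg = _small_problem(11, epochs=2)
    broken = [LearningExample(SOURCE, e.compound, e.dose, e.vitro_replicate,
                              e.vivo_replicate, e.input_vector, None)
              for e in source]
    with pytest.raises(ValueError):
        train(broken, target, cfg)


# -- collapse detection and restarts ---------------------------------------------------


def test_collapse_detector_cases():
    # all-human predictions over the window -> collapsed
    assert detect_mode_collapse([1.0, 1.0, 1.0], human_fractions=[1.0, 1.0, 1.0])
    # balanced -> not collapsed
    assert not detect_mode_collapse([0.5, 0.55, 0.52])
    # 96% for 3 epochs with threshold 0.95, window 3 -> collapsed
    assert detect_mode_collapse([0.96, 0.96, 0.96], threshold=0.95)
    # one epoch below the threshold breaks the window
    assert not detect_mode_collapse([0.96, 0.94, 0.96], threshold=0.95)
    # dominance alternating between classes is not a single-class collapse
    assert not detect_mode_collapse([0.96, 0.96], human_fractions=[0.96, 0.04])
    # empty or non-finite windows never report collapse
    assert not detect_mode_collapse([])
    assert not detect_mode_collapse([float("nan")] * 3)


def test_restarts_single_clean_run():
    source, target, cfg = _small_problem(12, epochs=4)
    _, report = train_with_restarts(source, target, cfg, max_restarts=3)
    assert report["runs"] == 1 and report["collapsed"] is False


def test_restarts_with_injected_collapse(monkeypatch):
    source, target, cfg = _small_problem(13, epochs=3)
    collapsing_seeds = {cfg.seed, cfg.seed + 1}

    def fake_collapsed(model, config):
        return config.seed in collapsing_seeds

    monkeypatch.setattr(net, "model_collapsed", fake_collapsed)
    model, report = train_with_restarts(source, target, cfg, max_restarts=3)
    assert report["runs"] == 3 and report["collapsed"] is False
    assert model.training_config.seed == cfg.seed + 2


def test_restarts_exhausted_returns_flagged_best(monkeypatch):
    source, target, cfg = _small_problem(14, epochs=3)
    monkeypatch.setattr(net, "model_collapsed", lambda m, c: True)
    with pytest.warns(UserWarning, match="collapsed"):
        model, report = train_with_restarts(source, target, cfg, max_restarts=0)
    assert report["collapsed"] is True and report["runs"] == 1
    assert model is not None


# -- prediction and persistence ----------------------------------------------------------


def test_predict_in_vivo_contract(tiny_data, tiny_examples):
    ds, _ = tiny_data
    norm, source, target = tiny_examples
    cfg = TrainingConfig(epochs=5, batch_size=32, seed=2)
    model = train(source, target, cfg, gene_set=ds.gene_set,
                  normalizer=norm.normalization)
    compound = ds.compounds[0]
    rat = ds.get("rat_vitro", compound, "high")[0]
    human = ds.get("human_vitro", compound, "high")[0]
    p1 = model.predict_in_vivo(rat)
    p2 = model.predict_in_vivo(rat)
    assert np.array_equal(p1, p2)  # identical inputs -> identical predictions
    assert p1.shape == (len(ds.gene_set), 4)
    assert np.all((p1 > 0) & (p1 < 1))
    p_h = model.predict_in_vivo(human)
    assert not np.array_equal(p1, p_h)  # not input-invariant across species
    denorm = model.predict_in_vivo(rat, denormalize=True)
    assert np.allclose(norm.normalization.transform(denorm), p1, atol=1e-9)


def test_checkpoint_round_trip(tmp_path, tiny_data, tiny_examples):
    ds, _ = tiny_data
    norm, source, target = tiny_examples
    cfg = TrainingConfig(epochs=3, batch_size=32, seed=4)
    model = train(source, target, cfg, gene_set=ds.gene_set,
                  normalizer=norm.normalization)
    path = tmp_path / "ckpt.json"
    model.save(path)
    back = DANNModel.load(path, expect_gene_set=ds.gene_set)
    x = source[0].input_vector
    assert np.array_equal(model.forward(x)[0], back.forward(x)[0])
    assert back.training_config == cfg
    assert back.gene_set.genes == ds.gene_set.genes


def test_checkpoint_hash_and_gene_set_guards(tmp_path, tiny_data, tiny_examples):
    ds, _ = tiny_data
    norm, source, target = tiny_examples
    model = train(source, target, TrainingConfig(epochs=2, batch_size=32, seed=4),
                  gene_set=ds.gene_set, normalizer=norm.normalization)
    path = tmp_path / "ckpt.json"
    model.save(path)
    other = GeneSet("other", tuple(f"x{i}" for i in range(len(ds.gene_set))))
    with pytest.raises(GeneSetMismatchError):
        DANNModel.load(path, expect_gene_set=other)
    blob = path.read_text().replace("toxtransfer-checkpoint-v1",
                                    "toxtransfer-checkpoint-v2")
    path.write_text(blob)
    with pytest.raises(CheckpointError):
        DANNModel.load(path)
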