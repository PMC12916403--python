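"""Architecture contracts: shapes, output ranges, determinism, freezing."""

import numpy as np
import pytest

from ppg2ecg import autodiff as ad, models
from ppg2ecg.autodiff import Tensor, grad


@pytest.fixture(scope="module")
def gen_reduced():
    return models.Generator(models.reduced_generator_config(max_tokens=600),
                            np.random.default_rng(0))


@pytest.fixture(scope="module")
def critic_reduced():
    return models.Discriminator(models.reduced_discriminator_config(),
                                np.random.default_rng(1))


def test_generator_default_520_in_520_out():
    g = models.Generator(models.GeneratorConfig(), np.random.default_rng(2))
    with ad.no_grad():
        out = g(Tensor(np.random.default_rng(3).uniform(-1, 1, (1, 520))))
    assert out.shape == (1, 520)
    assert np.abs(out.data).max() < 1.0


@pytest.mark.parametrize("t", [520, 1040, 521, 2080])
def test_generator_preserves_length_with_pad_and_crop(gen_reduced, t, rng):
    with ad.no_grad():
        assert gen_reduced(Tensor(rng.uniform(-1, 1, (1, t)))).shape == (1, t)


def test_generator_output_in_open_unit_interval(gen_reduced, rng):
    with ad.no_grad():
        out = gen_reduced(Tensor(rng.uniform(-1, 1, (3, 520)))).data
    assert np.abs(out).max() < 1.0


def test_generator_deterministic_in_inference(gen_reduced, rng):
    x = Tensor(rng.uniform(-1, 1, (2, 520)))
    gen_reduced.eval()
    with ad.no_grad():
        a, b = gen_reduced(x).data, gen_reduced(x).data
    assert np.array_equal(a, b)


def test_generator_rejects_empty_input(gen_reduced):
    with pytest.raises(ValueError):
        gen_reduced(Tensor(np.zeros((1, 1, 0))))


def test_generator_gradient_step_reduces_reconstruction(rng):
    g = models.Generator(models.reduced_generator_config(),
                         np.random.default_rng(7))
    x = Tensor(rng.uniform(-1, 1, (1, 520)))
    y = Tensor(rng.uniform(-0.5, 0.5, (1, 520)))
    params = g.parameters()
    from ppg2ecg.training import Adam
    opt = Adam(params, lr=1e-3)
    l0 = ((g(x) - y) ** 2).mean()
    opt.step(grad(l0, params))
    assert ((g(x) - y) ** 2).mean().item() < l0.item()


def test_critic_mode_contracts(critic_reduced, rng):
    x = Tensor(rng.uniform(-1, 1, (4, 520)))
    with ad.no_grad():
        score, emb, z = critic_reduced(x, mode="critic")
        logits, c, _ = critic_reduced(x, mode="pretext")
    assert score.shape == (4,)                       # unbounded scalar score
    assert emb.shape == (4, 2 * critic_reduced.cfg.d_model)
    assert logits.shape == (4, 6)                    # six binary heads
    assert z.shape[1] == critic_reduced.cfg.n_tokens + 1
    with pytest.raises(ValueError):
        critic_reduced(x, mode="bogus")


def test_default_critic_embedding_is_512_dimensional(rng):
    d = models.Discriminator(models.DiscriminatorConfig(),
                             np.random.default_rng(5))
    with ad.no_grad():
        _, emb, _ = d(Tensor(rng.uniform(-1, 1, (2, 520))))
    assert emb.shape == (2, 512)


def test_masked_head_exists_and_outputs_per_token(critic_reduced, rng):
    with ad.no_grad():
        pred, _, _ = critic_reduced(Tensor(rng.uniform(-1, 1, (2, 520))),
                                    mode="masked")
    assert pred.shape == (2, critic_reduced.cfg.n_tokens + 1)


def test_freezing_contract(rng):
    """With Transformer blocks frozen, their tensors are bit-identical after
    a fine-tuning step while head parameters change."""
    from ppg2ecg import preprocess as pp, training
    d = models.Discriminator(models.reduced_discriminator_config(),
                             np.random.default_rng(11))
    g = models.Generator(models.reduced_generator_config(),
                         np.random.default_rng(12))
    t = np.arange(520) / 130
    pairs = [pp.SegmentPair("s", np.sin(2 * np.pi * (1 + 0.1 * i) * t) * 0.9,
                            np.cos(2 * np.pi * (1 + 0.1 * i) * t) * 0.9,
                            4.0, 130.0, 0.0, pp.NormParams(-1, 1, -1, 1))
             for i in range(4)]
    frozen_before = {id(p): p.data.copy() for p in d.transformer_parameters()}
    head_before = d.critic_out.weight.data.copy()
    cfg = training.TrainConfig(epochs=1, batch=4, critic_steps_per_gen=1,
                               seed=3)
    training.train_gan(pairs, g, d, cfg, training.GPParams(6.0),
                       freeze_transformer=True, steps_per_epoch=1)
    for p in d.transformer_parameters():
        assert np.array_equal(p.data, frozen_before[id(p)])
    assert not np.array_equal(d.critic_out.weight.data, head_before)


def test_config_invariants():
    with pytest.raises(ValueError):
        models.GeneratorConfig(d_model=63)
    with pytest.raises(ValueError):
        models.DiscriminatorConfig(ffn_dim=500)
    with pytest.raises(ValueError):
        models.GeneratorConfig(depth=2)          # channel list mismatch


# -- AF classifiers ---------------------------------------------------------

@pytest.fixture(scope="module")
def af_cfg():
    return models.AFClassifierConfig(hidden=8, fc_units=16, dropout=0.0)


def test_bidlstm_probability_and_determinism(af_cfg, rng):
    m = models.BidLSTM(af_cfg, np.random.default_rng(21)).eval()
    x = Tensor(rng.normal(size=(3, 64)))
    with ad.no_grad():
        p1, p2 = m(x).data, m(x).data
    assert p1.shape == (3,)
    assert np.all((p1 >= 0) & (p1 <= 1))
    assert np.array_equal(p1, p2)
    with ad.no_grad():
        rev = m(Tensor(x.data[:, ::-1].copy())).data
    assert rev.shape == p1.shape


def test_cnnlstm_pooling_arithmetic_and_range(af_cfg, rng):
    m = models.CNNLSTM(af_cfg, np.random.default_rng(22), conv_channels=4)
    x = Tensor(rng.normal(size=(2, 1, 100)))
    with ad.no_grad():
        h = m.pool2(ad.relu(m.conv2(m._pad_right(
            m.pool1(ad.relu(m.conv1(m._pad_right(x))))))))
    assert h.shape[2] == (100 // 2) // 2
    with ad.no_grad():
        p = m(Tensor(rng.normal(size=(2, 100)))).data
    assert np.all((p >= 0) & (p <= 1))
    with pytest.raises(ValueError):
        m(Tensor(rng.normal(size=(1, 8))))


def test_cnnlstm_has_conv_parameters_beyond_bidlstm(af_cfg):
    bl = models.BidLSTM(af_cfg, np.random.default_rng(23))
    cl = models.CNNLSTM(af_cfg, np.random.default_rng(24), conv_channels=4)
    conv_params = sum(p.size for p in cl.conv1.parameters()
                      + cl.conv2.parameters())
    assert conv_params > 0
    assert len(list(cl.named_parameters())) > len(list(bl.named_parameters()))
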