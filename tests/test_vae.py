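import numpy as np
import pytest

from cardiovae.vae import (
    LatentPosterior,
    ShapeError,
    VAEConfig,
    VAEParams,
    decode,
    encode,
    extract_latent,
    init_params,
    kl_divergence,
    load_params,
    loss_and_grads,
    reconstruction_loss,
    reparameterize,
    save_params,
    total_loss,
    train,
)


def _tiny_params(seed=0, m_x=3, m_y=4, k=2, hidden=(5, 4), act="relu"):
    cfg = VAEConfig(latent_dim=k, hidden=hidden, activation=act)
    return init_params(m_x, m_y, cfg, np.random.default_rng(seed)), cfg


def _tiny_batch(rng, n=6, m=7):
    return rng.uniform(0.05, 0.95, size=(n, m))


def test_encode_decode_shapes_and_range(rng):
    params, _ = _tiny_params()
    t = _tiny_batch(rng)
    post = encode(t[:, :3], t[:, 3:], params)
    assert post.mu.shape == (6, 2) and post.log_var.shape == (6, 2)
    z = reparameterize(post, np.zeros_like(post.mu))
    assert np.allclose(z, post.mu)  # eps = 0 returns the posterior mean
    x_hat, y_hat = decode(z, params)
    assert x_hat.shape == (6, 3) and y_hat.shape == (6, 4)
    out = np.concatenate([x_hat, y_hat], axis=1)
    assert out.min() > 0.0 and out.max() < 1.0


def test_shape_mismatches_raise(rng):
    params, _ = _tiny_params()
    t = _tiny_batch(rng)
    with pytest.raises(ShapeError):
        encode(t[:, :2], t[:, 2:], params)
    with pytest.raises(ShapeError):
        decode(np.zeros((4, 3)), params)
    post = encode(t[:, :3], t[:, 3:], params)
    with pytest.raises(ShapeError):
        reparameterize(post, np.zeros((2, 2)))


def test_encode_rejects_non_finite(rng):
    params, _ = _tiny_params()
    t = _tiny_batch(rng)
    t[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        encode(t[:, :3], t[:, 3:], params)


def test_reconstruction_loss_is_per_sample_sum():
    v = np.zeros((4, 5))
    vp = np.full((4, 5), 0.1)
    # (1/n) sum_i ||v_i - v'_i||^2 = 5 * 0.01
    assert reconstruction_loss(v, vp) == pytest.approx(0.05)


def test_kl_is_nonnegative_and_zero_only_at_prior(rng):
    mu = rng.normal(size=(10, 3))
    lv = rng.normal(scale=0.5, size=(10, 3))
    assert kl_divergence(LatentPosterior(mu=mu, log_var=lv)) > 0
    assert kl_divergence(
        LatentPosterior(mu=np.zeros((10, 3)), log_var=np.zeros((10, 3)))
    ) == 0.0


def test_total_loss_combines_linearly():
    comp = total_loss(2.0, 0.5, beta=0.1)
    assert comp.total == pytest.approx(2.05)
    with pytest.raises(ValueError):
        total_loss(1.0, 1.0, beta=-1)


def test_train_is_deterministic(small_dataset):
    from cardiovae.preprocess import preprocess

    pp = preprocess(small_dataset)
    cfg = VAEConfig(latent_dim=3, hidden=(16, 8), iterations=40,
                    kl_warmup=10, seed=5)
    p1, t1 = train(pp, cfg)
    p2, t2 = train(pp, cfg)
    for k in p1.weights:
        assert np.array_equal(p1.weights[k], p2.weights[k])
    assert np.array_equal(t1.train_loss, t2.train_loss)


def test_train_reduces_loss(small_dataset):
    from cardiovae.preprocess import preprocess

    pp = preprocess(small_dataset)
    cfg = VAEConfig(latent_dim=4, hidden=(24, 12), iterations=200,
                    kl_warmup=0, seed=1)
    _, trace = train(pp, cfg)
    start = trace.train_loss[:10].mean()
    end = trace.train_loss[-10:].mean()
    assert end < 0.75 * start


def test_train_rejects_unscaled_data(rng):
    bad = rng.normal(size=(20, 5)) * 10
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        train(bad, VAEConfig(latent_dim=2, hidden=(4, 3), iterations=5))


def test_extract_latent_requires_training(rng):
    params, _ = _tiny_params()
    with pytest.raises(ValueError, match="untrained"):
        extract_latent(_tiny_batch(rng), params)


def test_params_round_trip(tmp_path, rng):
    params, cfg = _tiny_params()
    params.trained = True
    save_params(params, tmp_path / "w.npz")
    back = load_params(tmp_path / "w.npz")
    assert back.trained and back.latent_dim == params.latent_dim
    assert back.hidden == params.hidden and back.m_x == params.m_x
    for k in params.weights:
        assert np.array_equal(back.weights[k], params.weights[k])
    t = _tiny_batch(rng)
    a = encode(t[:, :3], t[:, 3:], params)
    b = encode(t[:, :3], t[:, 3:], back)
    assert np.allclose(a.mu, b.mu)


def test_loss_and_grads_matches_forward_losses(rng):
    params, _ = _tiny_params(act="linear")
    t = _tiny_batch(rng)
    eps = rng.standard_normal((6, 2))
    comp, grads = loss_and_grads(params.weights, t, eps, 0.3, "linear")
    post = encode(t[:, :3], t[:, 3:], params)
    z = reparameterize(post, eps)
    x_hat, y_hat = decode(z, params)
    recon = reconstruction_loss(t, np.concatenate([x_hat, y_hat], axis=1))
    kl = kl_divergence(post)
    assert comp.reconstruction == pytest.approx(recon)
    assert comp.kl == pytest.approx(kl)
    assert comp.total == pytest.approx(recon + 0.3 * kl)
    assert set(grads) == set(params.weights)
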