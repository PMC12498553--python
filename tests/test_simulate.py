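import numpy as np
import pandas as pd
import pytest

from cardiovae.simulate import (
    GROUPS,
    ConfigurationError,
    OmicsDataset,
    SimConfig,
    default_gene_means,
    default_metabolite_means,
    generate_dataset,
    inject_batch_effects,
    with_two_batches,
)


def test_shapes_names_and_ids(small_dataset):
    d = small_dataset
    assert d.x.shape == (60, 15)
    assert d.y.shape == (60, 20)
    assert d.x.index.equals(d.y.index)
    assert d.sample_ids.is_unique
    assert list(d.group.unique()) == list(GROUPS)
    assert (d.group.value_counts() == 10).all()
    assert "ATP" in d.x.columns and "Sirt1" in d.y.columns


def test_same_seed_reproduces_exactly():
    a = generate_dataset(SimConfig(seed=3))
    b = generate_dataset(SimConfig(seed=3))
    assert a.x.equals(b.x) and a.y.equals(b.y)
    c = generate_dataset(SimConfig(seed=4))
    assert not a.x.equals(c.x)


def test_zero_noise_returns_exact_group_means():
    d = generate_dataset(SimConfig(n_per_group=2, noise_cv=0.0, seed=0))
    met = default_metabolite_means()
    gen = default_gene_means()
    for g in GROUPS:
        rows = d.group == g
        assert np.allclose(d.x.loc[rows], met.loc[g].to_numpy())
        assert np.allclose(d.y.loc[rows], gen.loc[g].to_numpy())


def test_noise_is_unit_mean_multiplicative():
    # with many samples the empirical group mean converges to the
    # configured mean: the log-normal noise is centred to unit mean
    d = generate_dataset(SimConfig(n_per_group=2000, noise_cv=0.2, seed=1))
    met = default_metabolite_means()
    for g in ("A", "D"):
        emp = d.x.loc[d.group == g].mean()
        rel = np.abs(emp / met.loc[g] - 1.0)
        assert rel.max() < 0.02


def test_anchored_atp_means():
    met = default_metabolite_means()
    assert list(met.loc[list(GROUPS), "ATP"]) == [20, 22, 25, 27, 24, 26]
    gen = default_gene_means()
    assert gen.loc["A", "Sirt1"] == 4.2 and gen.loc["D", "Sirt1"] == 6.8


def test_batch_effect_is_exact_log_scale_distortion():
    base = generate_dataset(SimConfig(n_per_group=2, seed=5))
    assignment = {s: "b2" if s.startswith("A") else "b1"
                  for s in base.sample_ids}
    shifted = inject_batch_effects(
        base, {"b1": 0.0, "b2": 0.3}, {"b1": 1.0, "b2": 1.1}, assignment
    )
    rows = [s for s in base.sample_ids if s.startswith("A")]
    expected = np.exp(1.1 * np.log(base.x.loc[rows].to_numpy()) + 0.3)
    assert np.allclose(shifted.x.loc[rows].to_numpy(), expected)
    others = [s for s in base.sample_ids if not s.startswith("A")]
    assert np.allclose(shifted.x.loc[others], base.x.loc[others])
    assert set(shifted.batch) == {"b1", "b2"}


def test_batch_effect_validation():
    base = generate_dataset(SimConfig(n_per_group=1, seed=0))
    with pytest.raises(ConfigurationError, match="without batch assignment"):
        inject_batch_effects(base, {"b": 0.0}, {"b": 1.0}, {"A01": "b"})
    full = {s: "b" for s in base.sample_ids}
    with pytest.raises(ConfigurationError, match="must be > 0"):
        inject_batch_effects(base, {"b": 0.0}, {"b": -1.0}, full)


def test_with_two_batches_builds_valid_config():
    cfg = with_two_batches(SimConfig(n_per_group=4, seed=2), shift=0.5)
    d = generate_dataset(cfg)
    assert set(d.batch) == {"batch1", "batch2"}
    assert (d.batch.value_counts() == 12).all()


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError):
        SimConfig(n_per_group=0).validate()
    with pytest.raises(ConfigurationError):
        SimConfig(noise_cv=-0.1).validate()
    bad = default_metabolite_means().drop(index="F")
    with pytest.raises(ConfigurationError, match="missing"):
        SimConfig(metabolite_means=bad).validate()


def test_dataset_dir_round_trip(tmp_path, small_dataset):
    small_dataset.to_dir(tmp_path / "d")
    back = OmicsDataset.from_dir(tmp_path / "d")
    assert np.array_equal(back.x.to_numpy(), small_dataset.x.to_numpy())
    assert np.array_equal(back.y.to_numpy(), small_dataset.y.to_numpy())
    assert list(back.group) == list(small_dataset.group)


def test_dataset_invariants_enforced():
    idx = pd.Index(["s1", "s2"], name="sample_id")
    x = pd.DataFrame([[1.0], [2.0]], index=idx, columns=["m"])
    y_bad = pd.DataFrame([[1.0], [-2.0]], index=idx, columns=["g"])
    grp = pd.Series(["A", "B"], index=idx)
    with pytest.raises(ValueError, match="negative"):
        OmicsDataset(x, y_bad, grp, grp)
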