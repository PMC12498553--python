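import numpy as np
import pandas as pd
import pytest

from cardiovae.preprocess import (
    PreprocessError,
    combat_correct,
    detect_outliers,
    inverse_log_transform,
    log_transform,
    preprocess,
    select_top_genes,
    zscore,
)
from cardiovae.simulate import SimConfig, generate_dataset, with_two_batches


def test_log_transform_round_trip(small_dataset):
    v = log_transform(small_dataset.x)
    back = inverse_log_transform(v)
    assert np.allclose(back.to_numpy(), small_dataset.x.to_numpy())


def test_log_transform_rejects_negative():
    df = pd.DataFrame({"a": [1.0, -0.5]})
    with pytest.raises(PreprocessError, match="negative"):
        log_transform(df)


def test_zscore_centres_and_scales(small_dataset):
    z, means, sds, dropped = zscore(small_dataset.y)
    assert dropped == []
    assert np.abs(z.mean(axis=0)).max() < 1e-12
    assert np.abs(z.std(axis=0, ddof=1) - 1).max() < 1e-12
    back = z * sds + means
    assert np.allclose(back.to_numpy(), small_dataset.y.to_numpy())


def test_zscore_drops_constant_genes_with_warning():
    y = pd.DataFrame({"g1": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
    with pytest.warns(UserWarning, match="flat"):
        z, _, _, dropped = zscore(y)
    assert dropped == ["flat"]
    assert list(z.columns) == ["g1"]


# ---------------------------------------------------------------------------
# ComBat


def _batched_dataset(shift=0.5, scale=1.0, seed=11, n=10):
    cfg = with_two_batches(
        SimConfig(n_per_group=n, seed=seed), shift=shift, scale=scale
    )
    return generate_dataset(cfg)


def test_combat_removes_batch_shift_and_keeps_group_effect():
    clean = generate_dataset(SimConfig(n_per_group=10, seed=11))
    batched = _batched_dataset(shift=0.5, seed=11)
    v = log_transform(batched.x)
    corrected = combat_correct(v, batched.batch, batched.group)

    def batch_gap(m):
        return (m.loc[batched.batch == "batch2"].mean()
                - m.loc[batched.batch == "batch1"].mean()).abs().mean()

    assert batch_gap(corrected) < 0.05 * batch_gap(v)

    # the A-vs-D group contrast survives correction
    ref = log_transform(clean.x)
    for m in (corrected, ref):
        gap = (m.loc[batched.group == "D", "Lactate"].mean()
               - m.loc[batched.group == "A", "Lactate"].mean())
        assert gap > 0.5


def test_combat_single_batch_is_identity(small_dataset):
    v = log_transform(small_dataset.x)
    out = combat_correct(v, small_dataset.batch, small_dataset.group)
    assert np.array_equal(out.to_numpy(), v.to_numpy())


def test_combat_rejects_confounded_design():
    d = generate_dataset(SimConfig(n_per_group=4, seed=0))
    batch = d.group.rename("batch")  # batch identical to condition
    with pytest.raises(PreprocessError, match="confounded"):
        combat_correct(log_transform(d.x), batch, d.group)


def test_combat_rejects_singleton_batch(small_dataset):
    batch = pd.Series("b1", index=small_dataset.sample_ids)
    batch.iloc[0] = "lonely"
    with pytest.raises(PreprocessError, match="fewer than 2"):
        combat_correct(log_transform(small_dataset.x), batch,
                       small_dataset.group)


# ---------------------------------------------------------------------------
# outlier detection


def test_planted_outlier_is_flagged(rng):
    v = pd.DataFrame(rng.normal(size=(30, 8)),
                     index=[f"s{i}" for i in range(30)])
    v.iloc[4] += 12.0
    flags = detect_outliers(v)
    assert flags["s4"]
    assert flags.sum() == 1


def test_duplicated_rows_never_trigger_cluster_rule(rng):
    base = rng.normal(size=(10, 6))
    v = pd.DataFrame(np.vstack([base, base]),
                     index=[f"s{i}" for i in range(20)])
    details = detect_outliers(v, return_details=True)
    assert not details["cluster_flag"].any()


def test_outlier_requires_four_samples(rng):
    v = pd.DataFrame(rng.normal(size=(3, 4)))
    with pytest.raises(PreprocessError, match="at least 4"):
        detect_outliers(v)


def test_outlier_null_rate_is_modest(rng):
    # on homogeneous Gaussian data the flag rate stays low
    rates = []
    for _ in range(20):
        v = pd.DataFrame(rng.normal(size=(40, 10)))
        rates.append(detect_outliers(v).mean())
    assert np.mean(rates) < 0.05


# ---------------------------------------------------------------------------
# gene selection


def test_select_top_genes_orders_by_significance(small_dataset):
    sel = select_top_genes(small_dataset.y, small_dataset.group, n=5)
    assert len(sel.selected) == 5
    ps = sel.table.loc[sel.selected, "p_value"]
    assert (ps.to_numpy() == np.sort(sel.table["p_value"])[:5]).all()
    assert set(sel.table.columns) == {"log2fc", "p_value", "neg_log10_p",
                                      "contrast"}


def test_select_top_genes_validation(small_dataset):
    with pytest.raises(PreprocessError, match="reference"):
        select_top_genes(small_dataset.y, small_dataset.group, reference="Z")
    with pytest.raises(PreprocessError, match="more genes"):
        select_top_genes(small_dataset.y, small_dataset.group, n=999)


# ---------------------------------------------------------------------------
# full chain


def test_preprocess_outputs_unit_interval(small_dataset):
    pp = preprocess(small_dataset)
    for block in (pp.x_t, pp.y_t):
        assert block.to_numpy().min() >= 0.0
        assert block.to_numpy().max() <= 1.0
    mat = pp.matrix(include_outliers=True)
    assert mat.shape == (60, 35)
    assert mat.columns[0].startswith("met:")
    assert mat.columns[-1].startswith("gene:")


def test_preprocess_keeps_most_samples(small_dataset):
    pp = preprocess(small_dataset)
    # well-separated conditions must not be wiped out as outliers
    assert pp.outlier_flags.sum() <= 3
    assert (pp.groups().value_counts() >= 8).all()


def test_inverse_transform_recovers_raw_scale(small_dataset):
    pp = preprocess(small_dataset)
    x, y = pp.inverse_transform(pp.x_t, pp.y_t)
    assert np.allclose(x.to_numpy(), small_dataset.x.to_numpy())
    assert np.allclose(y.to_numpy(), small_dataset.y.to_numpy())


def test_preprocess_with_batches_runs_combat():
    batched = _batched_dataset(shift=0.6, seed=3)
    pp = preprocess(batched)
    mat = pp.matrix(include_outliers=True)
    gap = (mat.loc[batched.batch == "batch2"].mean()
           - mat.loc[batched.batch == "batch1"].mean()).abs().mean()
    assert gap < 0.05
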