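"""Shared fixtures: canonical phantoms and a small trained dose engine."""

from __future__ import annotations

import numpy as np
import pytest

from mrtdose import augment, dosesim, engine, phantom


@pytest.fixture(scope="session")
def head():
    """One default synthetic rat-head phantom with tumor mask."""
    return phantom.generate_synthetic_head(1)


@pytest.fixture(scope="session")
def prepared_head(head):
    """Default head with bolus added and re-cropped to the 96-layer frame."""
    grid, mask = head
    grid = phantom.add_bolus(grid, 5.0)
    pad = grid.shape[0] - mask.shape[0]
    mask = phantom.TumorMask(
        np.concatenate([np.zeros((pad,) + mask.shape[1:], bool), mask.mask])
    )
    grid, mask = phantom.crop_to_depth(grid, mask, 96)
    return grid, mask


@pytest.fixture(scope="session")
def water_grid():
    """Homogeneous water phantom in the canonical frame."""
    labels = np.full(phantom.CANONICAL_SHAPE, phantom.WATER, dtype=np.int8)
    return phantom.MaterialGrid(labels=labels)


def _materialize(bases, sample, regime, seed_pair):
    grid, mask = bases[sample.base_id]
    tgrid, tmask = augment.apply_transform(grid, mask, sample.transform)
    tgrid = phantom.add_bolus(tgrid, 5.0)
    pad = tgrid.shape[0] - tmask.mask.shape[0]
    tmask = phantom.TumorMask(
        np.concatenate([np.zeros((pad,) + tmask.mask.shape[1:], bool), tmask.mask])
    )
    tgrid, tmask = phantom.crop_to_depth(tgrid, tmask, 96)
    density = phantom.materials_to_density(tgrid)
    peak, valley = dosesim.surrogate_truth(tgrid)
    lam = dosesim.noise_lambdas(regime)
    noisy_peak = dosesim.simulate_replicates(peak, lam["peak"], 20, seed_pair[0])
    noisy_valley = dosesim.simulate_replicates(valley, lam["valley"], 20, seed_pair[1])
    return {
        "density": density.density,
        "materials": tgrid,
        "tumor": tmask.mask,
        "peak_truth": peak,
        "valley_truth": valley,
        "peak_noisy": noisy_peak,
        "valley_noisy": noisy_valley,
    }


def make_cohort_records(
    seed: int,
    n_bases: dict[str, int],
    n_samples: dict[str, int],
    regime: str = "high",
):
    """Generate a fully materialized synthetic cohort (helper for tests)."""
    bases, split = {}, {}
    idx = 0
    for part in ("train", "val", "test"):
        for _ in range(n_bases[part]):
            s = int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))
            bases[f"rat{idx:02d}"] = phantom.generate_synthetic_head(s)
            split[f"rat{idx:02d}"] = part
            idx += 1
    cohort = augment.build_augmented_cohort(bases, n_samples, split, seed=seed)
    records = {}
    for i, sample in enumerate(cohort):
        ss = np.random.SeedSequence([seed, 1000 + i])
        pair = [int(x % (2**31)) for x in ss.generate_state(2)]
        records[sample.sample_id] = (sample, _materialize(bases, sample, regime, pair))
    return records


def stack_partition(records, part: str, channel: str, target: str = "noisy"):
    """(inputs, targets) arrays of shape (N, D, H, W, 1) for one partition."""
    xs, ys = [], []
    for sid in sorted(records):
        sample, rec = records[sid]
        if sample.partition != part:
            continue
        xs.append(rec["density"][..., None])
        ys.append(rec[f"{channel}_{target}"].values[..., None])
    return np.stack(xs).astype(np.float32), np.stack(ys).astype(np.float32)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small materialized cohort: 2/1/1 bases, 20/6/2 high-noise samples."""
    return make_cohort_records(
        seed=7,
        n_bases={"train": 2, "val": 1, "test": 1},
        n_samples={"train": 20, "val": 6, "test": 2},
    )


@pytest.fixture(scope="session")
def tiny_engine(tiny_cohort):
    """A small valley model trained for a few epochs on the tiny cohort."""
    xtr, ytr = stack_partition(tiny_cohort, "train", "valley")
    xval, yval = stack_partition(tiny_cohort, "val", "valley")
    spec = engine.fit_normalization(xtr, ytr)
    tr = (engine.normalize_input(xtr, spec), engine.normalize_target(ytr, spec))
    va = (engine.normalize_input(xval, spec), engine.normalize_target(yval, spec))
    cfg = engine.UNetConfig(
        n_filters=4, batch_size=2, learning_rate=3e-3, levels=4,
        patience=25, max_epochs=20, adam_beta2=0.99,
    )
    model = engine.build_model(cfg, seed=5)
    model, history = engine.train_model(model, tr, va, cfg, seed=5)
    return model, spec, history
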