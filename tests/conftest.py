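import numpy as np
import pytest

import bodycomp as bc


@pytest.fixture(scope="session")
def desk_spec():
    return bc.PhantomSpec.desk(seed=123)


@pytest.fixture(scope="session")
def noise_free_spec():
    return bc.PhantomSpec.desk(seed=124, noise_sd_hu=0.0)


@pytest.fixture(scope="session")
def phantom(desk_spec):
    return bc.generate_phantom(desk_spec)


@pytest.fixture(scope="session")
def noise_free_phantom(noise_free_spec):
    return bc.generate_phantom(noise_free_spec)


@pytest.fixture(scope="session")
def desk_std():
    return bc.StandardizeConfig.desk()


@pytest.fixture(scope="session")
def desk_projection(phantom, desk_std):
    """Standardized, network-padded coronal projection of the session phantom."""
    vol, gt = phantom
    mask = bc.body_mask(vol)
    pre = bc.preprocess.precrop(vol, mask)
    raw = bc.coronal_max_projection(pre.volume, pre.mask)
    proj = bc.network_pad(
        bc.standardize(raw, vol.spacing_mm[0], pre.crop_offset_mm, desk_std), desk_std)
    return proj


@pytest.fixture(scope="session")
def overfit_seg_model():
    """A small body-composition net overfit on a handful of phantom slices.

    Used by inference tests that need a working (not necessarily accurate)
    model; trained at unit-test scale.
    """
    specs = [bc.PhantomSpec.desk(seed=200 + i) for i in range(4)]
    slices, labels = zip(*(bc.generate_l3_slice(s) for s in specs))
    x = bc.hu_to_unit(np.stack(slices))[..., None]
    y = np.stack([lm.labels for lm in labels]).astype(np.int64)
    model = bc.build_unet(bc.UNetConfig(depth=3, base_filters=8, n_classes=5, seed=0))
    model, _ = bc.train_model(
        model, (x, y), (x, y),
        bc.TrainConfig(max_epochs=40, learning_rate=3e-3, seed=0, patience=1000))
    return model


@pytest.fixture(scope="session")
def overfit_l3_model(desk_std):
    """A small L3-detection net overfit on a few phantom projections."""
    specs = [bc.PhantomSpec.desk(seed=300 + i) for i in range(4)]
    xs, ys = [], []
    for s in specs:
        vol, gt = bc.generate_phantom(s)
        mask = bc.body_mask(vol)
        pre = bc.preprocess.precrop(vol, mask)
        raw = bc.coronal_max_projection(pre.volume, pre.mask)
        proj = bc.network_pad(
            bc.standardize(raw, vol.spacing_mm[0], pre.crop_offset_mm, desk_std), desk_std)
        xs.append(bc.hu_to_unit(proj.image))
        ys.append(bc.make_l3_target(gt.l3_z_mm, proj.provenance, proj.image.shape))
    x = np.stack(xs)[..., None]
    y = np.stack(ys).astype(np.int64)
    model = bc.build_unet(bc.UNetConfig(depth=3, base_filters=8, n_classes=2, seed=1))
    model, _ = bc.train_model(
        model, (x, y), (x, y),
        bc.TrainConfig(max_epochs=100, learning_rate=1e-3, batch_size=2,
                       seed=1, patience=1000))
    return model
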