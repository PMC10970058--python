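"""Data kit: the 7:2:1 split rule, factor-10 augmentation, the synthetic
candling-image generator, and folder loading."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from PIL import Image

from peggnet.data import (AugmentSpec, EggGrade, EggLabel, GRADE_OF,
                          SplitSpec, SyntheticEggParams,
                          augment_training_set, compute_normalization_stats,
                          generate_synthetic_dataset, load_image_folder,
                          preprocess, render_egg, split_counts, split_dataset)

#: Class totals of the curated image set and the published per-class split.
CLASS_TOTALS = {"QP": 692, "PP": 332, "BYP": 523, "YYP": 323, "IP": 257}
EXPECTED_SPLIT = {
    "QP": (484, 138, 70),
    "PP": (232, 66, 34),
    "BYP": (366, 104, 53),
    "YYP": (226, 64, 33),
    "IP": (179, 51, 27),
}


def test_label_taxonomy():
    assert [l.name for l in EggLabel] == ["QP", "PP", "BYP", "YYP", "IP"]
    assert EggLabel.QP.grade == EggGrade.QP
    assert EggLabel.IP.grade == EggGrade.IP
    for l in (EggLabel.PP, EggLabel.BYP, EggLabel.YYP):
        assert GRADE_OF[l] == EggGrade.SP


def test_split_counts_reproduce_published_grid():
    """Floor-floor-remainder on the class totals gives every published cell."""
    for name, total in CLASS_TOTALS.items():
        assert split_counts(total) == EXPECTED_SPLIT[name]
    sums = [sum(split_counts(t)[i] for t in CLASS_TOTALS.values())
            for i in range(3)]
    assert sums == [1487, 423, 217]
    assert sum(sums) == 2127


@settings(max_examples=50, derandomize=True, deadline=None)
@given(sizes=st.lists(st.integers(1, 400), min_size=5, max_size=5),
       seed=st.integers(0, 2**16))
def test_split_is_a_partition(sizes, seed):
    items = {label: [f"{label.name}_{i}" for i in range(n)]
             for label, n in zip(EggLabel, sizes)}
    split = split_dataset(items, SplitSpec(seed=seed))
    subsets = [set(x for x, _ in s) for s in (split.train, split.val,
                                              split.test)]
    everything = set(x for xs in items.values() for x in xs)
    assert subsets[0] | subsets[1] | subsets[2] == everything
    assert not (subsets[0] & subsets[1] or subsets[0] & subsets[2]
                or subsets[1] & subsets[2])
    for label, n in zip(EggLabel, sizes):
        tr, va, te = split_counts(n)
        assert sum(1 for _, l in split.train if l == label) == tr
        assert sum(1 for _, l in split.val if l == label) == va
        assert sum(1 for _, l in split.test if l == label) == te


def test_split_rejects_bad_inputs():
    with pytest.raises(ValueError):
        SplitSpec(ratios=(0.7, 0.2, 0.2))
    with pytest.raises(ValueError):
        split_dataset({EggLabel.QP: []})


def test_split_shuffle_is_seeded():
    items = {EggLabel.QP: list(range(50))}
    a = split_dataset(items, SplitSpec(seed=3))
    b = split_dataset(items, SplitSpec(seed=3))
    c = split_dataset(items, SplitSpec(seed=4))
    assert a.train == b.train
    assert a.train != c.train


@pytest.mark.parametrize("factor", [1, 3, 10])
def test_augmentation_count_and_labels(factor, rng):
    imgs = [(rng.integers(0, 255, (16, 16, 3), dtype=np.uint8), label)
            for label in EggLabel for _ in range(2)]
    out = augment_training_set(imgs, AugmentSpec(factor=factor, seed=0))
    assert len(out) == factor * len(imgs)
    # labels preserved, blockwise per source image
    for i, (img, label) in enumerate(imgs):
        block = out[i * factor : (i + 1) * factor]
        assert all(l == label for _, l in block)
        # copy 1 is the identity
        np.testing.assert_array_equal(np.asarray(block[0][0]), img)
        assert all(np.asarray(im).shape == img.shape for im, _ in block)


def test_augmentation_is_byte_identical_under_seed(rng):
    imgs = [(rng.integers(0, 255, (24, 24, 3), dtype=np.uint8), EggLabel.QP)
            for _ in range(3)]
    a = augment_training_set(imgs, AugmentSpec(seed=11))
    b = augment_training_set(imgs, AugmentSpec(seed=11))
    c = augment_training_set(imgs, AugmentSpec(seed=12))
    assert all(np.array_equal(np.asarray(x), np.asarray(y))
               for (x, _), (y, _) in zip(a, b))
    assert any(not np.array_equal(np.asarray(x), np.asarray(y))
               for (x, _), (y, _) in zip(a, c))


def test_augmentation_rejects_factor_zero():
    with pytest.raises(ValueError):
        AugmentSpec(factor=0)


# ---------------------------------------------------------------------------
# synthetic generator


def test_generator_is_deterministic_under_seed():
    params = SyntheticEggParams(image_size=48, seed=5)
    a = generate_synthetic_dataset(params, {l: 2 for l in EggLabel})
    b = generate_synthetic_dataset(params, {l: 2 for l in EggLabel})
    for (ia, la), (ib, lb) in zip(a, b):
        assert la == lb
        np.testing.assert_array_equal(ia, ib)


def test_generator_rejects_bad_sizes():
    with pytest.raises(ValueError):
        render_egg(EggLabel.QP, np.random.default_rng(0),
                   SyntheticEggParams(image_size=0))
    with pytest.raises(ValueError):
        generate_synthetic_dataset(SyntheticEggParams(image_size=32),
                                   {EggLabel.QP: -1})


def _luminance(img):
    return np.asarray(img, dtype=float).mean()


def test_class_luminance_ordering():
    """IP (opaque) is darker than QP and PP on average; QP brightest body."""
    params = SyntheticEggParams(image_size=64, seed=9)
    data = generate_synthetic_dataset(params, {l: 8 for l in EggLabel})
    mean_by = {}
    for label in EggLabel:
        imgs = [im for im, l in data if l == label]
        mean_by[label] = np.mean([_luminance(im) for im in imgs])
    assert mean_by[EggLabel.IP] < mean_by[EggLabel.PP]
    assert mean_by[EggLabel.IP] < mean_by[EggLabel.QP]
    assert mean_by[EggLabel.PP] < mean_by[EggLabel.QP]


def test_byp_boundary_more_irregular_than_qp():
    """Radial variance of the dark-yolk boundary: BYP >> QP."""
    from scipy import ndimage

    params = SyntheticEggParams(image_size=96, seed=13)
    rng = np.random.default_rng(3)

    def boundary_radius_var(label):
        variances = []
        for _ in range(6):
            img = render_egg(label, rng, params).astype(float).mean(axis=2)
            # the yolk is the dark blob that does NOT touch the border
            # (the background does)
            labelled, n = ndimage.label(img < 60)
            border = set(labelled[0]) | set(labelled[-1]) | \
                set(labelled[:, 0]) | set(labelled[:, -1])
            sizes = ndimage.sum_labels(np.ones_like(labelled), labelled,
                                       range(1, n + 1))
            interior = [k + 1 for k in np.argsort(sizes)[::-1]
                        if k + 1 not in border]
            ys, xs = np.nonzero(labelled == interior[0])
            cy, cx = ys.mean(), xs.mean()
            r = np.hypot(ys - cy, xs - cx)
            theta = np.arctan2(ys - cy, xs - cx)
            # max radius per angular bin traces the boundary
            bins = np.digitize(theta, np.linspace(-np.pi, np.pi, 24))
            prof = [r[bins == b].max() for b in np.unique(bins)]
            variances.append(np.var(prof / np.mean(prof)))
        return np.mean(variances)

    assert boundary_radius_var(EggLabel.BYP) > 2 * boundary_radius_var(
        EggLabel.QP)


def test_pixel_statistics_classifier_beats_chance(small_synthetic_set):
    """Nearest-centroid on (mean RGB, luminance) must beat the 20% floor —
    the generator is non-degenerate for training smoke tests."""
    feats, labels = [], []
    for img, label in small_synthetic_set:
        x = np.asarray(img, dtype=float)
        feats.append([x[..., 0].mean(), x[..., 1].mean(), x[..., 2].mean(),
                      x.mean()])
        labels.append(label.value)
    feats = np.asarray(feats)
    labels = np.asarray(labels)
    centroids = np.stack([feats[labels == k].mean(axis=0) for k in range(5)])
    preds = np.linalg.norm(feats[:, None] - centroids[None], axis=2).argmin(1)
    assert (preds == labels).mean() > 0.4  # chance is 0.2


def test_generator_writes_class_folders(tmp_path):
    params = SyntheticEggParams(image_size=32, seed=1)
    generate_synthetic_dataset(params, {l: 2 for l in EggLabel},
                               out_dir=tmp_path)
    loaded = load_image_folder(tmp_path)
    assert {l.name for l in loaded} == {"QP", "PP", "BYP", "YYP", "IP"}
    assert all(len(v) == 2 for v in loaded.values())
    assert loaded[EggLabel.QP][0].shape == (32, 32, 3)


# ---------------------------------------------------------------------------
# folder loading and preprocessing


def test_load_rejects_unknown_subdir(tmp_path):
    (tmp_path / "foo").mkdir()
    with pytest.raises(ValueError, match="QP"):
        load_image_folder(tmp_path)


def test_load_warns_on_empty_and_corrupt(tmp_path):
    d = tmp_path / "QP"
    d.mkdir()
    with pytest.warns(UserWarning, match="no images"):
        out = load_image_folder(tmp_path)
    assert out[EggLabel.QP] == []
    Image.fromarray(np.zeros((8, 8, 3), dtype=np.uint8)).save(d / "ok.png")
    (d / "bad.png").write_bytes(b"not a png")
    with pytest.warns(UserWarning, match="unreadable"):
        out = load_image_folder(tmp_path)
    assert len(out[EggLabel.QP]) == 1


def test_load_missing_root():
    with pytest.raises(FileNotFoundError):
        load_image_folder("/nonexistent/dataset")


def test_preprocess_shape_and_normalization(rng):
    img = rng.integers(0, 255, (100, 140, 3), dtype=np.uint8)
    x = preprocess(img, input_size=56)
    assert x.shape == (3, 56, 56)
    assert x.dtype == np.float32
    mean, std = compute_normalization_stats([img])
    xn = preprocess(img, input_size=56, mean=mean, std=std)
    assert abs(xn.mean()) < 0.25  # roughly centered after normalization
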