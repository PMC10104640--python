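"""Segmentation: metrics, augmentation, corrections, network mechanics."""

import numpy as np
import pytest

from vasq.segmentation import (
    ADD,
    KEEP,
    REMOVE,
    SegModelConfig,
    apply_corrections,
    assd,
    augment,
    build_dau_gan,
    classical_segment,
    cross_validate,
    dsc,
    rotation_angles,
    segment,
    train,
)

from conftest import phantom_bundle, vessel_patch

TINY = dict(widths=(4, 8), disc_widths=(4, 8), epochs=2, batch_size=2, learning_rate=1e-3)


# ---------------------------------------------------------------------------
# metrics (hand-computed fixtures)
# ---------------------------------------------------------------------------


def test_dsc_hand_fixtures():
    a = np.zeros((8, 8), np.uint8)
    a[2:4, 2:4] = 1
    assert dsc(a, a) == 1.0
    b = np.zeros((8, 8), np.uint8)
    b[6:8, 6:8] = 1
    assert dsc(a, b) == 0.0
    # |A| = |B| = 4, overlap 2 -> 2*2 / 8 = 0.5
    c = np.zeros((8, 8), np.uint8)
    c[2:4, 3:5] = 1
    assert dsc(a, c) == 0.5
    assert dsc(np.zeros((4, 4)), np.zeros((4, 4))) == 1.0


def test_dsc_symmetry_and_shape_check():
    rng = np.random.default_rng(0)
    a = (rng.random((12, 12)) > 0.5).astype(np.uint8)
    b = (rng.random((12, 12)) > 0.5).astype(np.uint8)
    assert dsc(a, b) == dsc(b, a)
    with pytest.raises(ValueError):
        dsc(a, np.zeros((5, 5)))


def test_assd_hand_fixtures():
    a = np.zeros((10, 10), np.uint8)
    a[4:7, 4:7] = 1
    assert assd(a, a) == 0.0
    p = np.zeros((10, 10), np.uint8)
    q = np.zeros((10, 10), np.uint8)
    p[5, 2] = 1
    q[5, 5] = 1
    assert assd(p, q) == 3.0
    with pytest.raises(ValueError, match="empty"):
        assd(p, np.zeros((10, 10), np.uint8))


def test_assd_symmetric_and_translation_bounded():
    rng = np.random.default_rng(1)
    a = np.zeros((20, 20), np.uint8)
    a[5:12, 6:15] = 1
    b = np.roll(a, 1, axis=1)
    assert assd(a, b) == assd(b, a)
    # brute-force oracle over all boundary pixel pairs
    from vasq.segmentation import _boundary

    pa = np.argwhere(_boundary(a != 0))
    pb = np.argwhere(_boundary(b != 0))
    dists_ab = [min(np.hypot(*(p - q)) for q in pb) for p in pa]
    dists_ba = [min(np.hypot(*(q - p)) for p in pa) for q in pb]
    expected = (sum(dists_ab) + sum(dists_ba)) / (len(pa) + len(pb))
    assert assd(a, b) == pytest.approx(expected)
    assert assd(a, b) <= 1.0


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def test_rotation_set_has_89_distinct_angles():
    angles = rotation_angles()
    assert len(angles) == 89
    assert len(set(angles)) == 89
    assert angles[0] == 4 and angles[-1] == 356
    assert all(a % 4 == 0 and 0 < a < 360 for a in angles)


def test_symmetric_disk_invariant_under_180_rotation():
    rr, cc = np.mgrid[:41, :41]
    disk = ((rr - 20) ** 2 + (cc - 20) ** 2 <= 100).astype(np.uint8)
    img = disk * 120.0 + 50
    pairs = list(augment(img, disk, rotations=True, n_jitter=0))
    rot180 = pairs[2 + rotation_angles().index(180)]
    assert np.array_equal(rot180[1], disk)


def test_masks_stay_binary_and_jitter_leaves_mask_untouched():
    b = phantom_bundle(seed=1)
    rng = np.random.default_rng(0)
    img, mask = vessel_patch(b, rng)
    out = list(augment(img, mask, seed=5, rotations=False, n_jitter=3))
    assert len(out) == 2 + 3  # flips + jitters
    for a_img, a_mask in out:
        assert set(np.unique(a_mask)).issubset({0, 1})
    for a_img, a_mask in out[2:]:  # photometric only
        assert np.array_equal(a_mask, mask)
        assert not np.array_equal(a_img, img)


def test_rotation_keeps_image_and_mask_registered():
    """Rotate then un-rotate: away from the interpolation border the mask
    must match the original (checked through an eroded DSC)."""
    from scipy import ndimage

    b = phantom_bundle(seed=1)
    img, mask = vessel_patch(b, np.random.default_rng(3))
    pairs = list(augment(img, mask, rotations=True, n_jitter=0))
    ang = 48
    _, rmask = pairs[2 + rotation_angles().index(ang)]
    back = ndimage.rotate(rmask, -ang, reshape=False, order=0)
    core = ndimage.binary_erosion(mask, iterations=2)
    if core.any():
        overlap = (back & core).sum() / core.sum()
        assert overlap > 0.95


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        list(augment(np.zeros((4, 4)), np.zeros((5, 5))))


# ---------------------------------------------------------------------------
# corrections
# ---------------------------------------------------------------------------


def test_all_keep_layer_is_identity():
    mask = (np.random.default_rng(0).random((10, 10)) > 0.5).astype(np.uint8)
    layer = np.full((10, 10), KEEP)
    assert np.array_equal(apply_corrections(mask, layer), mask)


def test_add_and_remove_applied_with_remove_precedence():
    mask = np.zeros((6, 6), np.uint8)
    mask[0, 0] = 1
    l1 = np.full((6, 6), KEEP)
    l1[2, 2] = ADD
    l2 = np.full((6, 6), KEEP)
    l2[2, 2] = REMOVE
    l2[0, 0] = REMOVE
    out = apply_corrections(mask, [l1, l2])
    assert out[2, 2] == 0  # remove wins over add
    assert out[0, 0] == 0
    with pytest.raises(ValueError):
        apply_corrections(mask, np.zeros((3, 3)))


def test_restored_root_shifts_detection():
    """Deleting the injection-site blob makes root detection drift; an ADD
    correction layer restores it."""
    b = phantom_bundle(seed=2, noise_sd_gray=0.0)
    truth_rc = next(n.rc for n in b.truth_graph.nodes.values() if n.kind == "root")
    damaged = b.truth_mask.copy()
    r, c = truth_rc
    damaged[r - 30 : r + 30, c - 30 : c + 30] = 0
    layer = np.full(damaged.shape, KEEP)
    layer[r - 30 : r + 30, c - 30 : c + 30] = np.where(
        b.truth_mask[r - 30 : r + 30, c - 30 : c + 30], ADD, KEEP
    )
    repaired = apply_corrections(damaged, layer)
    assert np.array_equal(repaired, b.truth_mask)


# ---------------------------------------------------------------------------
# classical fallback
# ---------------------------------------------------------------------------


def test_classical_segment_recovers_phantom_mask():
    b = phantom_bundle(seed=4, noise_sd_gray=0.0)
    pred = classical_segment(b.bright_field)
    assert dsc(pred, b.truth_mask) >= 0.9


def test_classical_blank_image_is_empty():
    blank = np.full((128, 128), 220.0)
    assert classical_segment(blank).sum() == 0


def test_classical_inversion_symmetry():
    b = phantom_bundle(seed=4, noise_sd_gray=0.0)
    normal = classical_segment(b.bright_field)
    inverted = classical_segment(255.0 - b.bright_field, invert=True)
    assert np.array_equal(normal, inverted)


# ---------------------------------------------------------------------------
# network mechanics
# ---------------------------------------------------------------------------


def test_forward_pass_shape_and_range():
    gen, _ = build_dau_gan(SegModelConfig(**{**TINY, "epochs": 1}))
    x = np.random.default_rng(0).uniform(0, 1, (1, 1, 32, 32))
    y = gen.forward(x)
    assert y.shape == (1, 1, 32, 32)
    assert np.all((y >= 0) & (y <= 1))


def test_indivisible_input_size_raises_with_padding_hint():
    gen, _ = build_dau_gan(SegModelConfig(**{**TINY, "epochs": 1}))
    with pytest.raises(ValueError, match="pad"):
        gen.forward(np.zeros((1, 1, 33, 33)))


def test_attention_strictly_increases_parameter_count():
    base = dict(widths=(4, 8), disc_widths=(4, 8))
    with_attn, _ = build_dau_gan(SegModelConfig(attention=True, **base))
    without, _ = build_dau_gan(SegModelConfig(attention=False, **base))
    assert with_attn.n_parameters() > without.n_parameters()


def test_threshold_bounds():
    gen, _ = build_dau_gan(SegModelConfig(**{**TINY, "epochs": 1}))
    img = np.random.default_rng(0).uniform(0, 255, (32, 32))
    assert segment(img, gen, threshold=0.0).all()
    assert not segment(img, gen, threshold=1.0).any()


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="double"):
        SegModelConfig(widths=(8, 12))
    with pytest.raises(ValueError, match="lambda"):
        SegModelConfig(lambda_adv=-0.5)
    with pytest.raises(ValueError, match="positive"):
        SegModelConfig(widths=(0, 0))


def test_lambda_zero_trains_without_adversarial_terms():
    rng = np.random.default_rng(0)
    img = rng.uniform(0, 255, (16, 16))
    mask = (rng.random((16, 16)) > 0.5).astype(np.uint8)
    cfg = SegModelConfig(lambda_adv=0.0, **TINY)
    gen, disc = build_dau_gan(cfg)
    hist = train(gen, disc, [img], [mask], cfg)
    assert all("adv_loss" not in ep and "disc_loss" not in ep for ep in hist)
    assert all("seg_loss" in ep for ep in hist)


def test_training_is_deterministic_at_fixed_seed():
    rng = np.random.default_rng(0)
    imgs = [rng.uniform(0, 255, (16, 16)) for _ in range(3)]
    masks = [(rng.random((16, 16)) > 0.5).astype(np.uint8) for _ in range(3)]
    cfg = SegModelConfig(**TINY)
    h1 = train(*build_dau_gan(cfg), imgs, masks, cfg)
    h2 = train(*build_dau_gan(cfg), imgs, masks, cfg)
    assert h1 == h2


def test_empty_training_set_rejected():
    cfg = SegModelConfig(**TINY)
    with pytest.raises(ValueError, match="empty"):
        train(*build_dau_gan(cfg), [], [], cfg)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def test_fold_partition_is_even_and_reproducible():
    rng = np.random.default_rng(0)
    imgs = [rng.uniform(0, 255, (32, 32)) for _ in range(8)]
    masks = [(rng.random((32, 32)) > 0.7).astype(np.uint8) for _ in range(8)]
    cfg = SegModelConfig(folds=4, **TINY)
    df = cross_validate(imgs, masks, cfg, predictor="classical")
    assert sorted(df.fold.value_counts()) == [2, 2, 2, 2]
    assert sorted(df["sample"]) == list(range(8))
    df2 = cross_validate(imgs, masks, cfg, predictor="classical")
    assert (df["sample"].values == df2["sample"].values).all()


def test_perfect_predictor_scores_dsc_one_assd_zero(monkeypatch):
    import vasq.segmentation as seg

    rng = np.random.default_rng(0)
    masks = [(rng.random((32, 32)) > 0.7).astype(np.uint8) for _ in range(4)]
    imgs = [m * 255.0 for m in masks]
    monkeypatch.setattr(seg, "classical_segment", lambda im, **kw: (im > 127).astype(np.uint8))
    df = cross_validate(imgs, masks, SegModelConfig(folds=4, **TINY), predictor="classical")
    assert (df.dsc == 1.0).all()
    assert (df.assd == 0.0).all()


def test_too_few_samples_rejected():
    with pytest.raises(ValueError, match="at least"):
        cross_validate([np.zeros((8, 8))], [np.zeros((8, 8))], SegModelConfig(folds=4, **TINY))


def test_checkpoint_round_trip(tmp_path):
    from vasq.segmentation import load_model, save_model

    cfg = SegModelConfig(**{**TINY, "epochs": 1})
    rng = np.random.default_rng(0)
    img = rng.uniform(0, 255, (16, 16))
    mask = (rng.random((16, 16)) > 0.5).astype(np.uint8)
    gen, disc = build_dau_gan(cfg)
    train(gen, disc, [img], [mask], cfg)
    before = segment(img, gen)
    save_model(gen, tmp_path / "model.npz")
    restored = load_model(tmp_path / "model.npz")
    assert np.array_equal(segment(img, restored), before)
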