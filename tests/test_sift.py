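"""Scale space, keypoints, descriptors, distances and the selection rule."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from _oracles import brute_force_mean_min_distance
from medisr.fixtures import FixtureSpec, generate
from medisr.sift import (
    DESCRIPTOR_SIZE,
    EmptyFeatureSetError,
    FeatureSet,
    SelectionConfig,
    SiftFeature,
    describe_keypoints,
    detect_keypoints,
    extract_features,
    gaussian_scale_space,
    match_features,
    match_ratio,
    select_candidates,
    sift_distance,
)


def feature_set(descriptors, image_id="s"):
    feats = [
        SiftFeature(x=10.0 + i, y=10.0, scale=1.6, descriptor=np.asarray(d, dtype=float))
        for i, d in enumerate(descriptors)
    ]
    return FeatureSet(image_id=image_id, features=feats)


def unit_vec(axis, value=1.0):
    d = np.zeros(DESCRIPTOR_SIZE)
    d[axis] = value
    return d


# ----------------------------------------------------------- scale space
def test_constant_image_has_zero_dogs_and_no_keypoints():
    img = np.full((64, 64), 128, dtype=np.uint8)
    pyr = gaussian_scale_space(img)
    for octave in pyr.octaves:
        for dog in octave["dogs"]:
            assert np.allclose(dog, 0.0, atol=1e-12)
    assert detect_keypoints(pyr) == []


def test_single_bright_pixel_matches_sampled_gaussian():
    img = np.zeros((65, 65))
    img[32, 32] = 1.0
    sigma0 = 1.6
    pyr = gaussian_scale_space(img, octaves=1, sigma0=sigma0, assumed_blur=0.0)
    layer = pyr.octaves[0]["gaussians"][0]
    yy, xx = np.meshgrid(np.arange(65) - 32, np.arange(65) - 32, indexing="ij")
    expected = np.exp(-(yy**2 + xx**2) / (2 * sigma0**2)) / (2 * np.pi * sigma0**2)
    assert np.allclose(layer, expected, atol=2e-4)


def test_gaussian_semigroup_property(rng):
    img = rng.random((48, 48))
    s1, s2 = 1.2, 1.6
    twice = gaussian_filter(gaussian_filter(img, s1, mode="reflect"), s2, mode="reflect")
    once = gaussian_filter(img, np.hypot(s1, s2), mode="reflect")
    assert np.allclose(twice[8:-8, 8:-8], once[8:-8, 8:-8], atol=1e-3)


def test_octave_count_reduced_with_warning():
    img = np.zeros((20, 20))
    with pytest.warns(UserWarning, match="octaves"):
        pyr = gaussian_scale_space(img, octaves=5)
    assert len(pyr.octaves) < 5


# ------------------------------------------------------------ keypoints
def test_isolated_blob_detected_near_center():
    yy, xx = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
    cy, cx = 31.0, 35.0
    img = 30 + 180 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 3.0**2))
    pyr = gaussian_scale_space(img.astype(np.uint8))
    kps = detect_keypoints(pyr)
    assert kps, "no keypoint found on an isolated blob"
    dists = [np.hypot(k.y - cy, k.x - cx) for k in kps]
    assert min(dists) <= 2.0


def test_flat_ramp_yields_no_keypoints():
    img = generate(FixtureSpec(kind="ramp", height=64, width=64))
    assert detect_keypoints(gaussian_scale_space(img)) == []


def test_keypoint_count_stable_under_intensity_scaling(textured_image):
    pyr_a = gaussian_scale_space(textured_image.astype(np.float64) / 255.0)
    pyr_b = gaussian_scale_space(0.5 * textured_image.astype(np.float64) / 255.0)
    kps_a = detect_keypoints(pyr_a, contrast_threshold=0.01)
    kps_b = detect_keypoints(pyr_b, contrast_threshold=0.005)
    # halving intensities halves DoG values; halving the threshold too
    # must recover the same detections
    assert {(k.y, k.x, round(k.scale, 6)) for k in kps_a} == {
        (k.y, k.x, round(k.scale, 6)) for k in kps_b
    }


# ----------------------------------------------------------- descriptors
def test_descriptors_are_128d_nonneg_unit_norm(textured_image):
    fs = extract_features(textured_image, "tex")
    assert len(fs) > 0
    for f in fs.features:
        assert f.descriptor.shape == (DESCRIPTOR_SIZE,)
        assert (f.descriptor >= 0).all()
        assert np.linalg.norm(f.descriptor) == pytest.approx(1.0, abs=1e-9)
        assert 0.0 <= f.orientation < 360.0


def test_uniform_gradient_concentrates_orientation_mass():
    # a pure horizontal ramp has a single gradient direction; after
    # rotation to the dominant orientation all mass should land in one
    # orientation bin per cell
    yy, xx = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
    img = (2.0 * xx).astype(np.float64) / 255.0
    kp = SiftFeature(x=32.0, y=32.0, scale=1.6)
    feats, dropped = describe_keypoints(img, [kp])
    assert dropped == 0
    desc = feats[0].descriptor.reshape(4, 4, 8)
    for r in range(4):
        for c in range(4):
            cell = desc[r, c]
            assert cell.max() >= 0.999 * cell.sum()


def test_keypoints_near_border_dropped_with_count():
    img = generate(FixtureSpec(kind="smooth_noise", height=64, width=64, seed=2))
    kps = [SiftFeature(x=1.0, y=1.0, scale=1.6), SiftFeature(x=32.0, y=32.0, scale=1.6)]
    feats, dropped = describe_keypoints(img, kps)
    assert dropped == 1
    assert len(feats) == 1


def test_rotation_invariance_quarter_turn(textured_image):
    f0 = extract_features(textured_image, "orig")
    rot = np.rot90(textured_image).copy()
    f90 = extract_features(rot, "rot")
    w = textured_image.shape[1]
    dists = []
    for a in f0.features:
        ty, tx = w - 1 - a.x, a.y  # position map under rot90
        for b in f90.features:
            if np.hypot(b.y - ty, b.x - tx) < 1.5:
                dists.append(np.linalg.norm(a.descriptor - b.descriptor))
    assert len(dists) >= 5
    assert np.median(dists) < 0.25


# ------------------------------------------------------------- distances
def test_distance_zero_on_self(textured_image):
    fs = extract_features(textured_image, "tex")
    assert sift_distance(fs, fs) == 0.0


def test_distance_on_identical_subset():
    t = feature_set([unit_vec(0), unit_vec(1), unit_vec(2)], "t")
    s = feature_set([unit_vec(1), unit_vec(2)], "s")
    assert sift_distance(s, t) == 0.0


def test_distance_hand_value():
    s = feature_set([np.zeros(DESCRIPTOR_SIZE)], "s")
    t = feature_set([unit_vec(0, 1.0), unit_vec(0, 3.0)], "t")
    assert sift_distance(s, t) == pytest.approx(1.0)


def test_distance_matches_brute_force(rng):
    ds = np.abs(rng.random((5, DESCRIPTOR_SIZE)))
    dt = np.abs(rng.random((7, DESCRIPTOR_SIZE)))
    s = feature_set(list(ds), "s")
    t = feature_set(list(dt), "t")
    assert sift_distance(s, t) == pytest.approx(brute_force_mean_min_distance(ds, dt), rel=1e-12)


def test_distance_is_asymmetric():
    s = feature_set([unit_vec(0)], "s")
    t = feature_set([unit_vec(0), unit_vec(5)], "t")
    assert sift_distance(s, t) == 0.0
    assert sift_distance(t, s) > 0.0


def test_empty_sets_raise():
    empty = FeatureSet("e")
    full = feature_set([unit_vec(0)], "f")
    for a, b in ((empty, full), (full, empty), (empty, empty)):
        with pytest.raises(EmptyFeatureSetError):
            sift_distance(a, b)
    with pytest.raises(EmptyFeatureSetError):
        match_ratio(empty, full)


# ----------------------------------------------------------- match ratio
def test_match_ratio_identical_sets(textured_image):
    fs = extract_features(textured_image, "tex")
    assert match_ratio(fs, fs) == 1.0


def test_match_ratio_no_matches():
    s = feature_set([unit_vec(0)], "s")
    # two equidistant far references fail the ratio test
    t = feature_set([unit_vec(1), unit_vec(2)], "t")
    assert match_ratio(s, t) == 0.0


def test_match_ratio_two_of_four():
    # features 0 and 1 have exact twins in t; features 2 and 3 sit
    # equidistant from both t entries and fail the ratio test
    s = feature_set([unit_vec(0), unit_vec(1), unit_vec(4), unit_vec(5)], "s")
    t = feature_set([unit_vec(0), unit_vec(1)], "t")
    matches = match_features(s, t)
    assert len(matches) == 2
    assert match_ratio(s, t) == pytest.approx(0.5)


# -------------------------------------------------------------- selection
def test_candidate_identical_to_reference_admitted(textured_image):
    fs = extract_features(textured_image, "cand")
    ref = extract_features(textured_image, "ref")
    dec = select_candidates([fs], [ref])[0]
    assert dec.admitted
    assert dec.eta == 1.0
    assert dec.D == 0.0


def test_flat_candidate_rejected(textured_image):
    flat = extract_features(np.full((64, 64), 90, dtype=np.uint8), "flat")
    ref = extract_features(textured_image, "ref")
    dec = select_candidates([flat], [ref])[0]
    assert not dec.admitted
    assert dec.reason == "no keypoints"


def test_selection_matches_direct_rule_evaluation(large_texture):
    # textured candidates are crops of the reference-bearing texture;
    # flat candidates carry no keypoints
    ref = extract_features(large_texture[:96, :96], "ref")
    candidates = []
    for i, (r0, c0) in enumerate([(0, 0), (16, 16), (32, 0), (0, 32), (24, 24)]):
        candidates.append(extract_features(large_texture[r0 : r0 + 64, c0 : c0 + 64], f"tex{i}"))
    for i in range(5):
        candidates.append(
            extract_features(generate(FixtureSpec(kind="constant", height=64, width=64, seed=i)), f"flat{i}")
        )
    decisions = select_candidates(candidates, [ref])
    for dec, cand in zip(decisions, candidates):
        if len(cand) == 0:
            assert not dec.admitted
        else:
            expected = match_ratio(cand, ref) >= sift_distance(cand, ref)
            assert dec.admitted == expected
    assert sum(d.admitted for d in decisions) >= 3  # the matching crops pass
    assert not any(d.admitted for d in decisions[5:])


def test_selection_requires_nonempty_references():
    with pytest.raises(ValueError):
        select_candidates([], [FeatureSet("empty")])


def test_eta_threshold_override(textured_image):
    fs = extract_features(textured_image, "cand")
    ref = extract_features(textured_image, "ref")
    dec = select_candidates([fs], [ref], SelectionConfig(eta_threshold=1.1))[0]
    assert not dec.admitted
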