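"""Viterbi block search, path costs and neurite-object classification."""

import math

import numpy as np
import pytest

from rrstrace.errors import GeometryError, ParameterError
from rrstrace.imaging import GrayImage, Point, sample_zone
from rrstrace.hmm_tracer import (
    Chain,
    ChainNode,
    TracerConfig,
    candidate_headings,
    classify_node,
    heading_to_unit,
    path_log_cost,
    trace_from_seed,
    viterbi_block,
)
from rrstrace.seeding import Seed

from conftest import random_image


def brute_force_best(img, seed_pos, initial_fan, config):
    """Exhaustive enumeration oracle for the block search.

    Enumerates every candidate-heading sequence depth-first in candidate
    order (so the first strict maximum matches the lowest-index tie-break)
    and scores each full-depth path by summing per-step log costs.  Only
    valid for instances where no candidate ever leaves the image.
    """
    best = {"score": -math.inf, "path": None}
    r = config.step_length_r

    def recurse(pos, heading, depth, score, path):
        if depth == config.n_events:
            if score > best["score"]:
                best["score"] = score
                best["path"] = list(path)
            return
        if depth == 0:
            fan = candidate_headings(*initial_fan)
        else:
            fan = candidate_headings(heading, 90.0, config.k_step)
        for h in fan:
            nxt = pos + r * heading_to_unit(float(h))
            assert img.contains(nxt[0], nxt[1]), "oracle instance left bounds"
            step_cost = path_log_cost(
                img, Point(pos[0], pos[1]), Point(nxt[0], nxt[1]),
                config.spacing,
            )
            path.append(nxt)
            recurse(nxt, float(h), depth + 1, score + step_cost, path)
            path.pop()

    recurse(np.asarray(seed_pos, dtype=float), 0.0, 0, 0.0, [])
    return best["score"], np.array(best["path"])


def small_config(k_initial=3, k_step=2, n_events=3, **kw):
    return TracerConfig(step_length_r=3.0, n_events=n_events,
                        k_initial=k_initial, k_step=k_step, **kw)


class TestCandidateHeadings:
    def test_step_fan(self):
        assert candidate_headings(0.0, 90.0, 3).tolist() == [-45.0, 0.0, 45.0]

    def test_full_circle_eight(self):
        out = candidate_headings(123.0, 360.0, 8)
        assert out.tolist() == [0, 45, 90, 135, 180, 225, 270, 315]

    def test_reaction_fan(self):
        out = candidate_headings(180.0, 180.0, 5)
        assert out.tolist() == [90.0, 135.0, 180.0, 225.0, 270.0]

    def test_k_one_returns_center(self):
        assert candidate_headings(30.0, 90.0, 1).tolist() == [30.0]

    def test_invalid_k(self):
        with pytest.raises(ParameterError):
            candidate_headings(0.0, 90.0, 0)


class TestPathLogCost:
    def test_constant_closed_form(self, constant_image):
        cost = path_log_cost(constant_image, Point(0, 0), Point(0, 4), 1.0)
        assert cost == pytest.approx(5 * math.log(0.5))

    def test_monotone_in_brightness(self):
        dim = GrayImage(np.full((10, 10), 0.3))
        bright = GrayImage(np.full((10, 10), 0.8))
        c_dim = path_log_cost(dim, Point(5, 1), Point(5, 8), 1.0)
        c_bright = path_log_cost(bright, Point(5, 1), Point(5, 8), 1.0)
        assert c_bright > c_dim

    def test_ramp_matches_sample_oracle(self, ramp_image):
        cost = path_log_cost(ramp_image, Point(3, 2), Point(3, 6), 1.0)
        assert cost == pytest.approx(sum(math.log(v)
                                         for v in (0.2, 0.3, 0.4, 0.5, 0.6)))

    def test_degenerate_segment(self, constant_image):
        with pytest.raises(GeometryError):
            path_log_cost(constant_image, Point(1, 1), Point(1, 1), 1.0)


class TestViterbiBlock:
    @pytest.mark.parametrize("case", range(20))
    def test_matches_exhaustive_enumeration(self, case):
        rng = np.random.default_rng(1000 + case)
        img = random_image(rng)
        k_initial = int(rng.integers(2, 4))
        k_step = int(rng.integers(2, k_initial + 1))
        config = small_config(k_initial, k_step,
                              n_events=int(rng.integers(3, 5)))
        seed = np.array([16.0, 16.0]) + rng.uniform(-2, 2, 2)
        fan = (float(rng.uniform(0, 360)), 360.0, k_initial)
        block = viterbi_block(img, seed, fan, config)
        score, path = brute_force_best(img, seed, fan, config)
        assert block.score == score
        np.testing.assert_array_equal(block.positions[1:], path)

    def test_uniform_image_tie_break_lowest_index(self, constant_image):
        config = small_config()
        block = viterbi_block(constant_image, np.array([10.0, 10.0]),
                              (0.0, 360.0, 3), config)
        # all paths tie; candidate 0 (the fan's most counter-clockwise
        # heading) wins at every event
        assert block.headings_deg[0] == 0.0
        assert block.headings_deg[1] == -45.0
        assert block.headings_deg[2] == -90.0

    def test_trellis_truncated_at_border(self):
        img = GrayImage(np.full((7, 40), 0.5))
        config = small_config(n_events=4)
        block = viterbi_block(img, np.array([3.0, 3.0]), (0.0, 360.0, 2),
                              config)
        assert 1 <= block.n_steps <= 4

    def test_score_monotone_in_pixel_intensity(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            img = random_image(rng)
            config = small_config()
            seed = np.array([16.0, 16.0])
            fan = (0.0, 360.0, 3)
            base = viterbi_block(img, seed, fan, config).score
            brighter = img.pixels.copy()
            r, c = rng.integers(0, 32, 2)
            brighter[r, c] = min(1.0, brighter[r, c] + rng.uniform(0, 0.5))
            raised = viterbi_block(GrayImage(brighter), seed, fan, config).score
            assert raised >= base - 1e-12


class TestClassifyNode:
    def test_constant_is_background(self, constant_image):
        config = TracerConfig()
        assert classify_node(constant_image, Point(10, 2), Point(10, 7),
                             config) == 0

    def test_thin_ridge_is_object(self, ridge_image):
        config = TracerConfig(line_width=1.0)
        p0, p1 = Point(10, 5), Point(10, 15)
        assert classify_node(ridge_image, p0, p1, config) == 1
        # direct median/mean oracle on the same lattice
        prof = sample_zone(ridge_image, p0, p1, 1.0, 1.0)
        assert np.mean(prof.line_samples) == pytest.approx(0.9)
        assert np.median(prof.valid_zone_samples()) == pytest.approx(0.1)

    def test_filled_blob_is_background(self, blob_image):
        config = TracerConfig()
        # a segment strictly inside the bright square: the zone is equally
        # bright, so the median ties the mean and nothing is recognized
        assert classify_node(blob_image, Point(20, 12), Point(20, 20),
                             config) == 0

    def test_margin_zero_recovers_strict_rule(self, ridge_image):
        strict = TracerConfig(line_width=1.0, object_margin=0.0)
        prof = sample_zone(ridge_image, Point(10, 5), Point(10, 15), 1.0, 1.0)
        expected = int(np.median(prof.valid_zone_samples())
                       < np.mean(prof.line_samples))
        assert classify_node(ridge_image, Point(10, 5), Point(10, 15),
                             strict) == expected


class TestTraceFromSeed:
    def test_blank_image_dead_seed(self, constant_image):
        chain = trace_from_seed(constant_image, Seed(Point(10.0, 10.0)),
                                TracerConfig(max_nodes=50))
        assert not chain.stored
        assert chain.n_object_nodes == 0

    def test_short_ridge_not_stored(self):
        # a ridge spanning barely two steps yields at most two object
        # nodes, below the three-in-sequence storage requirement
        img_arr = np.full((41, 41), 0.1)
        img_arr[20, 18:29] = 0.9
        chain = trace_from_seed(GrayImage(img_arr), Seed(Point(20.0, 19.0)),
                                TracerConfig())
        assert chain.n_object_nodes <= 2
        assert not chain.stored

    def test_straight_phantom_tip_seed(self):
        from rrstrace.synthetic import PhantomSpec, generate_phantom

        spec = PhantomSpec(shape=(160, 160), n_trees=1,
                           branches_per_tree=(1, 1), branch_length=(100, 100),
                           branch_width=(2, 2), curvature_deg=0.0,
                           noise_sd=0.05, n_halo_spots=0, n_debris=0,
                           illum_gradient=0.0, rng_seed=1)
        img, truth = generate_phantom(spec)
        tip = truth.centerlines[0][0]
        chain = trace_from_seed(img, Seed(Point(float(tip[0]), float(tip[1]))),
                                TracerConfig())
        assert chain.stored
        line = truth.centerlines[0]
        from scipy.spatial import cKDTree

        tree = cKDTree(line)
        pos = np.array([[n.position.row, n.position.col]
                        for n in chain.nodes if n.is_object])
        d, _ = tree.query(pos)
        assert np.mean(d <= 2.0) >= 0.9

    def test_storage_rule_matches_flag_runs(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            img = random_image(rng, (64, 64))
            chain = trace_from_seed(img, Seed(Point(32.0, 32.0)),
                                    TracerConfig(max_nodes=60))
            flags = chain.object_flags
            best = run = 0
            for f in flags:
                run = run + 1 if f else 0
                best = max(best, run)
            assert chain.stored == (best >= 3)

    def test_deterministic(self):
        from rrstrace.synthetic import PhantomSpec, generate_phantom

        spec = PhantomSpec(shape=(128, 128), rng_seed=3)
        img, _ = generate_phantom(spec)
        config = TracerConfig()
        a = trace_from_seed(img, Seed(Point(64.0, 64.0)), config)
        b = trace_from_seed(img, Seed(Point(64.0, 64.0)), config)
        assert len(a.nodes) == len(b.nodes)
        for na, nb in zip(a.nodes, b.nodes):
            assert na.position == nb.position
            assert na.is_object == nb.is_object

    def test_consecutive_nodes_step_apart(self):
        from rrstrace.synthetic import PhantomSpec, generate_phantom

        spec = PhantomSpec(shape=(128, 128), rng_seed=5)
        img, _ = generate_phantom(spec)
        config = TracerConfig()
        chain = trace_from_seed(img, Seed(Point(64.0, 64.0)), config)
        for a, b in zip(chain.nodes, chain.nodes[1:]):
            assert a.position.distance_to(b.position) == pytest.approx(
                config.step_length_r, rel=1e-6)


class TestTracerConfig:
    @pytest.mark.parametrize("kw", [
        {"step_length_r": 1.0},
        {"n_events": 2},
        {"k_initial": 2, "k_step": 3},
        {"extend_min_run": 0},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ParameterError):
            TracerConfig(**kw)
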