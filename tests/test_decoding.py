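"""Pixel and spot-cluster decoding against closed forms and brute force."""

import numpy as np
import pandas as pd
import pytest

from merfish3d.codebook import generate_codebook
from merfish3d.decoding import (
    cluster_spots,
    decode_cluster,
    decode_pixels,
    decode_spot_clusters,
    estimate_scale_factors,
    normalized_codebook_matrix,
)
from merfish3d.stack import ImageStack
from merfish3d.synthetic import PlantedMoleculeSet, simulate_image_stack

from conftest import match_molecules

SINGLE_DROPOUT_DISTANCE = np.sqrt(2 - np.sqrt(3))  # ~0.5176
DOUBLE_DROPOUT_DISTANCE = np.sqrt(2 - np.sqrt(2))  # ~0.7654


class TestCodebookMatrix:
    def test_rows_unit_norm_with_half_entries(self, codebook16):
        m = normalized_codebook_matrix(codebook16)
        assert np.allclose(np.linalg.norm(m, axis=1), 1.0)
        assert np.allclose(m[m > 0], 0.5)

    def test_single_bit_corruptions_stay_decodable(self, codebook16):
        # every one-bit error leaves the true barcode nearest, within 0.6
        m = normalized_codebook_matrix(codebook16)
        b = codebook16.barcodes.astype(float)
        worst = 0.0
        for i, word in enumerate(b):
            flips = list(np.flatnonzero(word)) + list(np.flatnonzero(word == 0))
            for bit in flips:
                corrupted = word.copy()
                corrupted[bit] = 1 - corrupted[bit]
                v = corrupted / np.linalg.norm(corrupted)
                d = np.linalg.norm(m - v, axis=1)
                assert d.argmin() == i
                worst = max(worst, d[i])
        assert worst == pytest.approx(SINGLE_DROPOUT_DISTANCE, abs=1e-9)
        assert worst < 0.6


class TestClusterPath:
    def _spot(self, bit, y, x, brightness=100.0):
        return pd.DataFrame(
            {"bit": [bit], "z": [0.0], "y": [float(y)], "x": [float(x)],
             "brightness": [brightness]}
        )

    def test_colocated_spots_form_one_cluster(self, codebook16):
        on = np.flatnonzero(codebook16.barcodes[0])
        tables = [None] * 16
        for b in on:
            tables[b] = pd.DataFrame(
                {"z": [0.0], "y": [10.0], "x": [10.0], "brightness": [100.0]}
            )
        clusters = cluster_spots(tables)
        assert len(clusters) == 1
        assert len(clusters[0]) == 4

    def test_minimum_three_spots_rule(self):
        # sizes {4, 3, 2, 1} at well-separated sites -> 2 clusters kept
        sites = {(10, 10): 4, (30, 30): 3, (50, 50): 2, (70, 70): 1}
        rows_per_bit = [[] for _ in range(8)]
        for (y, x), size in sites.items():
            for b in range(size):
                rows_per_bit[b].append((0.0, float(y), float(x), 1.0))
        tables = [
            pd.DataFrame(rows, columns=["z", "y", "x", "brightness"])
            for rows in rows_per_bit
        ]
        clusters = cluster_spots(tables)
        assert len(clusters) == 2
        assert sorted(len(c) for c in clusters) == [3, 4]

    def test_molecules_beyond_radius_stay_separate(self):
        tables = []
        for b in range(4):
            tables.append(pd.DataFrame(
                {"z": [0.0, 0.0], "y": [10.0, 15.0], "x": [10.0, 10.0],
                 "brightness": [1.0, 1.0]}))
        clusters = cluster_spots(tables, radius=2.0)
        assert len(clusters) == 2  # 5 px > 2 px

    def test_drift_correction_reunites_spots(self):
        drift = np.zeros((4, 3), dtype=int)
        drift[2] = drift[3] = (0, 5, 5)
        tables = []
        for b in range(4):
            dy, dx = (5.0, 5.0) if b >= 2 else (0.0, 0.0)
            tables.append(pd.DataFrame(
                {"z": [0.0], "y": [10.0 + dy], "x": [10.0 + dx],
                 "brightness": [1.0]}))
        # without drift correction the spots split into two 2-spot groups,
        # both below the 3-spot minimum
        assert len(cluster_spots(tables, drift=None)) == 0
        clusters = cluster_spots(tables, drift=drift)
        assert len(clusters) == 1 and len(clusters[0]) == 4

    def test_exact_pattern_decodes_at_distance_zero(self, codebook16):
        on = np.flatnonzero(codebook16.barcodes[0])
        cluster = pd.DataFrame(
            {"bit": on, "z": 0.0, "y": 5.0, "x": 5.0, "brightness": 200.0}
        )
        gene, dist = decode_cluster(cluster, codebook16)
        assert gene == codebook16.names[0]
        assert dist == pytest.approx(0.0, abs=1e-12)

    def test_single_bit_dropout_corrected(self, codebook16):
        on = np.flatnonzero(codebook16.barcodes[0])[:3]
        cluster = pd.DataFrame(
            {"bit": on, "z": 0.0, "y": 5.0, "x": 5.0, "brightness": 200.0}
        )
        gene, dist = decode_cluster(cluster, codebook16)
        assert gene == codebook16.names[0]
        assert dist == pytest.approx(SINGLE_DROPOUT_DISTANCE, abs=1e-9)

    def test_double_dropout_unassigned(self, codebook16):
        on = np.flatnonzero(codebook16.barcodes[0])[:2]
        cluster = pd.DataFrame(
            {"bit": on, "z": 0.0, "y": 5.0, "x": 5.0, "brightness": 200.0}
        )
        gene, dist = decode_cluster(cluster, codebook16)
        assert gene is None
        assert dist == pytest.approx(DOUBLE_DROPOUT_DISTANCE, abs=1e-9)

    def test_full_cluster_path_recovers_planted_molecules(self, codebook16, psf):
        from merfish3d.spots import detect_spots

        planted = PlantedMoleculeSet(
            genes=[codebook16.names[i] for i in (0, 5, 9)],
            positions=[[0, 20, 20], [0, 60, 60], [0, 100, 40]],
            amplitudes=[8000.0] * 3,
            shape=(1, 128, 128),
        )
        stack, truth = simulate_image_stack(codebook16, planted)
        tables = [detect_spots(stack.data[b], psf, 3600, 0.25) for b in range(16)]
        mols = decode_spot_clusters(tables, codebook16)
        assert match_molecules(truth, mols) == 1.0


class TestPixelPath:
    def test_matches_brute_force_on_small_stack(self):
        # oracle: per-pixel nearest barcode by explicit loop
        cb = generate_codebook(16, 8, 0, seed=3)
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 1, (16, 1, 16, 16))
        data[data < 0.6] = 0.0
        stack = ImageStack(data=data)
        m = normalized_codebook_matrix(cb)
        expect = np.full((1, 16, 16), -1)
        for y in range(16):
            for x in range(16):
                v = data[:, 0, y, x]
                n = np.linalg.norm(v)
                if n < 1e-9:
                    continue
                d = np.linalg.norm(m - v / n, axis=1)
                if d.min() <= 0.6:
                    expect[0, y, x] = int(d.argmin())
        from merfish3d.decoding import _decode_pixel_maps

        gene_map, _, _ = _decode_pixel_maps(stack.data, m, 0.6)
        assert np.array_equal(gene_map, expect)

    def test_noiseless_recall_and_identity(self, codebook16, clean_stack):
        stack, truth = clean_stack
        mols = decode_pixels(stack, codebook16, min_pixels=2)
        assert match_molecules(truth, mols) == 1.0
        assert int(mols["is_blank"].sum()) == 0

    def test_single_bit_dropouts_still_decode(self, codebook16):
        from merfish3d.synthetic import plant_random_molecules

        planted = plant_random_molecules(codebook16, 100, (2, 256, 256), seed=8)
        name_to_idx = {n: i for i, n in enumerate(codebook16.names)}
        for m in range(len(planted.genes)):
            on = np.flatnonzero(codebook16.barcodes[name_to_idx[planted.genes[m]]])
            planted.dropout_bits[m] = int(on[m % 4])
        stack, truth = simulate_image_stack(codebook16, planted)
        mols = decode_pixels(stack, codebook16, min_pixels=2)
        assert match_molecules(truth, mols) == 1.0
        assert mols["min_distance"].max() < 0.6

    def test_all_zero_stack_decodes_nothing(self, codebook16):
        stack = ImageStack(data=np.zeros((16, 1, 8, 8)))
        assert len(decode_pixels(stack, codebook16)) == 0


class TestScaleFactors:
    def _fixture(self, codebook, gains, seed=0):
        from merfish3d.synthetic import plant_random_molecules

        planted = plant_random_molecules(codebook, 120, (2, 256, 256), seed=seed)
        stack, _ = simulate_image_stack(codebook, planted)
        stack.data *= np.asarray(gains)[:, None, None, None]
        return stack

    def test_uniform_gains_give_equal_factors(self, codebook16):
        stack = self._fixture(codebook16, np.ones(16))
        f = estimate_scale_factors(stack, codebook16, sample_z=None, seed=1)
        assert np.allclose(f, 1.0, rtol=0.02)

    def test_doubled_gain_bit_gets_half_factor(self, codebook16):
        gains = np.ones(16)
        gains[3] = 2.0
        stack = self._fixture(codebook16, gains)
        f = estimate_scale_factors(stack, codebook16, sample_z=None, seed=1)
        others = np.delete(f, 3)
        assert f[3] / others.mean() == pytest.approx(0.5, rel=0.05)

    def test_iteration_converges_to_fixed_point(self, codebook16):
        gains = np.ones(16)
        gains[5] = 1.5
        stack = self._fixture(codebook16, gains)
        f9 = estimate_scale_factors(stack, codebook16, n_iterations=9,
                                    sample_z=None, seed=2)
        f10 = estimate_scale_factors(stack, codebook16, n_iterations=10,
                                     sample_z=None, seed=2)
        assert np.abs(f10 / f9 - 1).max() < 0.01

    def test_empty_stack_raises_actionable_error(self, codebook16):
        stack = ImageStack(data=np.zeros((16, 1, 8, 8)))
        with pytest.raises(ValueError, match="threshold"):
            estimate_scale_factors(stack, codebook16, sample_z=None)
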