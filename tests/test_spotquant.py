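"""Rendering / spot detection closed loop and nascent counting."""

import numpy as np
import pandas as pd
import pytest

from fishkin import SimConfig, simulate_counts
from fishkin.render import ImageConfig, ellipsoid_mask, render_image
from fishkin.spotquant import (
    Spot,
    SpotParams,
    cellquants_from_counts,
    detect_spots,
    filter_spots_to_mask,
    identify_transcription_focus,
    nascent_count,
    quantify_batch,
    unit_intensity,
)

VOXEL = (200.0, 74.0, 74.0)


def _truth_row(M, focus, cell_id="c0"):
    return pd.Series({"cell_id": cell_id, "M": M, "focus_signal": focus})


def _match(found_nm, truth_nm, radius_nm=400.0):
    """Greedy one-to-one matching of detected vs true spot coordinates."""
    found = list(found_nm)
    hits = 0
    for t in truth_nm:
        if not found:
            break
        d = [np.linalg.norm(np.array(f) - np.array(t)) for f in found]
        i = int(np.argmin(d))
        if d[i] <= radius_nm:
            hits += 1
            found.pop(i)
    return hits


class TestRender:
    def test_empty_cell_is_background_only(self):
        cell = render_image(_truth_row(0, 0.0), seed=0, noise=False)
        assert np.allclose(cell.image, cell.config.background)

    def test_single_spot_integrates_to_unit(self):
        cfg = ImageConfig()
        cell = render_image(_truth_row(1, 0.0), cfg, seed=1, noise=False)
        assert (cell.image > cfg.background + 1).any()
        # rendering identity: total photons above background = one unit
        excess = (cell.image - cfg.background).sum()
        assert excess == pytest.approx(cfg.unit_photon_count, rel=0.01)

    def test_focus_rendered_inside_nucleus(self):
        cell = render_image(_truth_row(0, 3.0), seed=2, noise=False)
        vox = np.array(cell.truth["focus_coord_nm"]) / np.array(VOXEL)
        assert cell.nuclear_mask[tuple(np.round(vox).astype(int))]

    def test_stack_too_small_errors(self):
        cfg = ImageConfig(stack_shape=(6, 8, 8), min_separation_nm=5000.0)
        with pytest.raises(ValueError, match="too small"):
            render_image(_truth_row(200, 0.0), cfg, seed=3)


class TestDetectSpots:
    def test_background_only_yields_no_spots(self):
        rng = np.random.default_rng(0)
        img = rng.poisson(10.0, size=(20, 64, 64)).astype(float)
        assert detect_spots(img, VOXEL) == []

    def test_missing_voxel_metadata_errors(self):
        with pytest.raises(ValueError, match="anisotropy|voxel"):
            detect_spots(np.zeros((8, 8, 8)), None)

    def test_single_noiseless_spot_found_within_a_voxel(self):
        cell = render_image(_truth_row(1, 0.0), seed=4, noise=False)
        spots = detect_spots(cell.image, VOXEL)
        assert len(spots) == 1
        truth = np.array(cell.truth["spot_coords_nm"][0])
        found = np.array([spots[0].z, spots[0].y, spots[0].x])
        assert np.all(np.abs(found - truth) <= np.array(VOXEL))

    def test_integrated_intensity_is_linear_in_photon_scale(self):
        params = SpotParams(integrate_halfwidth_sigmas=5.0)
        intensities = []
        for scale in (5000.0, 10000.0):
            cfg = ImageConfig(unit_photon_count=scale)
            cell = render_image(_truth_row(1, 0.0), cfg, seed=5, noise=False)
            spots = detect_spots(cell.image, VOXEL, params)
            assert len(spots) == 1
            intensities.append(spots[0].integrated_intensity)
        assert intensities[1] / intensities[0] == pytest.approx(2.0, rel=0.01)

    @pytest.mark.parametrize("noise", [False, True])
    def test_fifty_spot_recall_and_precision(self, noise):
        # 50 well-separated spots (>= 3 sigma in the worst axis), SNR >= 10
        cfg = ImageConfig(
            stack_shape=(48, 160, 160),
            unit_photon_count=12000.0,
            min_separation_nm=1100.0,
        )
        cell = render_image(_truth_row(50, 0.0), cfg, seed=6, noise=noise)
        spots = detect_spots(cell.image, VOXEL)
        truth = cell.truth["spot_coords_nm"]
        found = [(s.z, s.y, s.x) for s in spots]
        hits = _match(found, truth)
        recall = hits / len(truth)
        precision = hits / max(len(found), 1)
        assert recall >= 0.98
        assert precision >= 0.98


class TestMaskFilter:
    def test_inside_identity_outside_empty(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[5, 5, 5] = True
        inside = Spot(x=5 * 74, y=5 * 74, z=5 * 200, integrated_intensity=1.0)
        outside = Spot(x=0, y=0, z=0, integrated_intensity=1.0)
        assert filter_spots_to_mask([inside], mask, VOXEL) == [inside]
        assert filter_spots_to_mask([outside], mask, VOXEL) == []

    def test_boundary_voxel_is_kept(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[2, 2, 2] = True  # true exactly at the centroid voxel
        s = Spot(x=2 * 74, y=2 * 74, z=2 * 200, integrated_intensity=1.0)
        assert filter_spots_to_mask([s], mask, VOXEL) == [s]


class TestFocus:
    def test_brightest_nuclear_spot_wins(self):
        spots = [
            Spot(0, 0, 0, 10.0, in_nucleus=True),
            Spot(0, 0, 0, 3.0, in_nucleus=True),
            Spot(0, 0, 0, 50.0, in_nucleus=False),
        ]
        focus = identify_transcription_focus(spots, unit=1.0)
        assert focus is spots[0]

    def test_no_nuclear_spots_gives_none(self):
        assert identify_transcription_focus([Spot(0, 0, 0, 5.0)], unit=1.0) is None

    def test_subthreshold_focus_not_called(self):
        spots = [Spot(0, 0, 0, 1.5, in_nucleus=True)]
        assert identify_transcription_focus(spots, unit=1.0) is None

    def test_tie_breaks_to_lowest_z_with_warning(self):
        a = Spot(0, 0, z=400.0, integrated_intensity=7.0, in_nucleus=True)
        b = Spot(0, 0, z=200.0, integrated_intensity=7.0, in_nucleus=True)
        with pytest.warns(UserWarning, match="tie"):
            focus = identify_transcription_focus([a, b], unit=1.0)
        assert focus is b


class TestUnitIntensity:
    def test_constant_batch(self):
        spots = [Spot(0, 0, 0, 100.0) for _ in range(25)]
        assert unit_intensity(spots) == 100.0

    def test_median_of_three_values(self):
        spots = [Spot(0, 0, 0, v) for v in [90.0, 100.0, 110.0] * 7]
        assert unit_intensity(spots) == 100.0

    def test_median_robust_to_bright_doublets(self):
        # 5% doublets at twice the intensity leave the median untouched;
        # brute-force median is the oracle
        vals = [100.0] * 95 + [200.0] * 5
        spots = [Spot(0, 0, 0, v) for v in vals]
        assert unit_intensity(spots) == float(np.median(vals)) == 100.0

    def test_too_few_spots_errors(self):
        with pytest.raises(ValueError, match="insufficient"):
            unit_intensity([Spot(0, 0, 0, 1.0)] * 5)

    def test_mean_mode(self):
        spots = [Spot(0, 0, 0, v) for v in [50.0] * 10 + [150.0] * 10]
        assert unit_intensity(spots, params=SpotParams(unit_stat="mean")) == 100.0


class TestNascentCount:
    def test_ratio_and_absent_focus(self):
        assert nascent_count(10 * 7.0, 7.0) == pytest.approx(10.0)
        assert nascent_count(0.0, 7.0) == 0.0

    def test_nonpositive_unit_errors(self):
        with pytest.raises(ValueError):
            nascent_count(5.0, 0.0)


class TestQuantifyBatchRoundTrip:
    def test_noiseless_roundtrip_recovers_truth(self, myc_model):
        # render a small batch and require the quantified N to agree with
        # the ground-truth focus signal within 2%
        cfg = ImageConfig(stack_shape=(40, 128, 128), min_separation_nm=900.0)
        rows = [
            {"cell_id": "c0", "M": 30, "focus_signal": 3.4},
            {"cell_id": "c1", "M": 25, "focus_signal": 4.1},
        ]
        batch = []
        for i, row in enumerate(rows):
            cell = render_image(pd.Series(row), cfg, seed=10 + i, noise=False)
            batch.append((row["cell_id"], cell.image, cell.cell_mask, cell.nuclear_mask))
        spots_df, quants = quantify_batch(batch, VOXEL)
        for row in rows:
            q = quants[quants["cell_id"] == row["cell_id"]].iloc[0]
            assert q["focus_called"]
            assert q["M"] == row["M"]
            assert q["N"] == pytest.approx(row["focus_signal"], rel=0.02)

    def test_unit_calibration_is_cell_order_invariant(self, myc_model):
        cfg = ImageConfig(min_separation_nm=900.0)
        rows = [
            {"cell_id": "a", "M": 24, "focus_signal": 3.0},
            {"cell_id": "b", "M": 28, "focus_signal": 2.5},
        ]
        cells = [
            (r["cell_id"],) + tuple(
                getattr(render_image(pd.Series(r), cfg, seed=20 + i, noise=False), k)
                for k in ("image", "cell_mask", "nuclear_mask")
            )
            for i, r in enumerate(rows)
        ]
        _, fwd = quantify_batch(cells, VOXEL)
        _, rev = quantify_batch(cells[::-1], VOXEL)
        assert fwd["unit_intensity"].iloc[0] == rev["unit_intensity"].iloc[0]
        merged = fwd.merge(rev, on="cell_id", suffixes=("_f", "_r"))
        assert np.allclose(merged["N_f"], merged["N_r"])


class TestBypass:
    def test_bypass_applies_focus_threshold(self, myc_model):
        counts = pd.DataFrame(
            {
                "cell_id": ["a", "b"],
                "M": [100, 90],
                "focus_signal": [3.5, 1.2],  # b is below the 2x unit floor
            }
        )
        q = cellquants_from_counts(counts)
        assert q.loc[0, "focus_called"] and q.loc[0, "N"] == 3.5
        assert not q.loc[1, "focus_called"]
        assert q.loc[1, "flag"] == "no focus called"
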