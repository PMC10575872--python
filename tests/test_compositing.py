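"""Cloud masking, gap-filling, median compositing and composite filtering."""

import datetime as dt

import numpy as np
import pytest

from swirmap import (
    apply_cloud_mask,
    build_annual_composite,
    filter_composites,
    gap_fill,
)
from swirmap.compositing import AnnualComposite

from conftest import make_scene


class TestCloudMask:
    def test_all_clear_leaves_validity_unchanged(self):
        s = make_scene(np.full((4, 4), 0.2))
        out = apply_cloud_mask(s)
        assert out.valid.all()
        np.testing.assert_array_equal(out.swir, s.swir)

    def test_flag_count_matches_invalidated_pixels(self):
        rng = np.random.default_rng(0)
        qa = np.zeros((100, 100), dtype=np.uint8)
        flat = rng.choice(10000, size=37, replace=False)
        qa.flat[flat] = 1
        s = make_scene(np.full((100, 100), 0.3), qa=qa)
        out = apply_cloud_mask(s)
        assert int((~out.valid).sum()) == 37
        np.testing.assert_array_equal(out.swir, s.swir)  # values untouched

    def test_all_cloud_invalidates_everything(self):
        s = make_scene(np.full((3, 3), 0.2), qa=np.ones((3, 3), dtype=np.uint8))
        assert not apply_cloud_mask(s).valid.any()

    def test_idempotent(self):
        qa = np.array([[0, 1], [2, 0]], dtype=np.uint8)
        s = make_scene(np.full((2, 2), 0.2), qa=qa)
        once = apply_cloud_mask(s)
        twice = apply_cloud_mask(once)
        np.testing.assert_array_equal(once.valid, twice.valid)
        np.testing.assert_array_equal(once.swir, twice.swir)


class TestGapFill:
    def _archive(self, values, base_date=dt.date(2005, 7, 1)):
        return [
            make_scene(
                np.full((2, 2), v),
                date=base_date + dt.timedelta(days=30 * i),
                scene_id=f"a{i}",
            )
            for i, v in enumerate(values)
        ]

    def test_fully_valid_scene_is_identity(self):
        s = make_scene(np.full((2, 2), 0.4))
        out = gap_fill(s, self._archive([0.1, 0.9]))
        np.testing.assert_array_equal(out.swir, s.swir)
        assert out.valid.all()

    def test_median_of_three_candidates(self):
        qa = np.zeros((2, 2), dtype=np.uint8)
        qa[0, 0] = 1
        s = apply_cloud_mask(make_scene(np.full((2, 2), 0.5), qa=qa))
        out = gap_fill(s, self._archive([0.1, 0.2, 0.3]))
        assert out.swir[0, 0] == pytest.approx(0.2)
        assert out.valid[0, 0]
        assert (out.swir.flat[1:] == 0.5).all()  # valid pixels never modified

    def test_empty_candidate_pool_stays_invalid(self):
        qa = np.ones((2, 2), dtype=np.uint8)
        s = apply_cloud_mask(make_scene(np.full((2, 2), 0.5), qa=qa))
        archive = [apply_cloud_mask(sc.copy()) for sc in self._archive([0.1])]
        for sc in archive:
            sc.valid[:] = False
        out = gap_fill(s, archive)
        assert not out.valid.any()

    def test_window_excludes_far_scenes_and_self(self):
        qa = np.zeros((2, 2), dtype=np.uint8)
        qa[1, 1] = 1
        s = apply_cloud_mask(
            make_scene(np.full((2, 2), 0.5), qa=qa, scene_id="self")
        )
        near = make_scene(
            np.full((2, 2), 0.2), date=s.date + dt.timedelta(days=300), scene_id="n"
        )
        far = make_scene(
            np.full((2, 2), 0.9), date=s.date + dt.timedelta(days=400), scene_id="f"
        )
        out = gap_fill(s, [s, near, far])
        assert out.swir[1, 1] == pytest.approx(0.2)  # far scene and self excluded

    def test_geometry_mismatch_errors(self):
        s = make_scene(np.full((2, 2), 0.5))
        bad = make_scene(np.full((3, 3), 0.5), scene_id="bad")
        with pytest.raises(ValueError, match="shape"):
            gap_fill(s, [bad])

    def test_never_invalidates(self):
        rng = np.random.default_rng(1)
        qa = (rng.random((2, 2)) < 0.4).astype(np.uint8)
        s = apply_cloud_mask(make_scene(rng.random((2, 2)), qa=qa))
        out = gap_fill(s, self._archive([0.3, 0.4]))
        assert (out.valid | ~s.valid).all()  # validity only grows


class TestAnnualComposite:
    def test_identical_scenes_reproduce_the_scene(self):
        vals = np.arange(25).reshape(5, 5) / 25.0
        scenes = [
            make_scene(vals, date=dt.date(2005, 7, d), scene_id=f"s{d}")
            for d in (1, 15, 29)
        ]
        comp = build_annual_composite(scenes, 2005)
        np.testing.assert_array_equal(comp.swir, vals)
        assert comp.masked_fraction == 0.0
        assert comp.n_scenes == 3
        assert comp.has_swir

    @pytest.mark.parametrize(
        "values, expected",
        [
            ([0.1, 0.2, 0.6], 0.2),  # odd count: middle value
            ([0.1, 0.2, 0.4, 0.9], 0.3),  # even count: mean of middle two
        ],
    )
    def test_median_conventions(self, values, expected):
        scenes = [
            make_scene(np.full((2, 2), v), date=dt.date(2005, 6, 1 + i), scene_id=f"s{i}")
            for i, v in enumerate(values)
        ]
        comp = build_annual_composite(scenes, 2005)
        assert comp.swir[0, 0] == pytest.approx(expected)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        scenes = [
            make_scene(rng.random((4, 4)), date=dt.date(2005, 7, 1 + i), scene_id=f"s{i}")
            for i in range(5)
        ]
        a = build_annual_composite(scenes, 2005)
        b = build_annual_composite(scenes[::-1], 2005)
        np.testing.assert_array_equal(a.swir, b.swir)

    def test_affine_equivariance(self):
        rng = np.random.default_rng(4)
        scenes = [
            make_scene(rng.random((4, 4)), date=dt.date(2005, 7, 1 + i), scene_id=f"s{i}")
            for i in range(4)
        ]
        mapped = [
            make_scene(0.5 * s.swir + 0.1, date=s.date, scene_id=s.scene_id)
            for s in scenes
        ]
        a = build_annual_composite(scenes, 2005)
        b = build_annual_composite(mapped, 2005)
        np.testing.assert_allclose(b.swir, 0.5 * a.swir + 0.1, rtol=0, atol=1e-15)

    def test_out_of_window_scenes_excluded(self):
        inside = make_scene(np.full((2, 2), 0.2), date=dt.date(2005, 7, 1))
        outside = make_scene(
            np.full((2, 2), 0.9), date=dt.date(2005, 5, 31), scene_id="may"
        )
        comp = build_annual_composite([inside, outside], 2005)
        assert comp.n_scenes == 1
        assert (comp.swir == 0.2).all()

    def test_no_swir_band_flagged(self):
        scenes = [make_scene(None, qa=np.zeros((2, 2), dtype=np.uint8))]
        comp = build_annual_composite(scenes, 2005)
        assert not comp.has_swir
        assert comp.masked_fraction == 1.0
        assert comp.n_scenes == 0

    def test_masked_pixels_become_nodata(self):
        qa = np.zeros((2, 2), dtype=np.uint8)
        qa[0, 0] = 1
        scenes = [apply_cloud_mask(make_scene(np.full((2, 2), 0.2), qa=qa))]
        comp = build_annual_composite(scenes, 2005)
        assert np.isnan(comp.swir[0, 0])
        assert comp.masked_fraction == pytest.approx(0.25)


class TestFilterComposites:
    def _comp(self, year, masked_fraction=0.0, has_swir=True):
        return AnnualComposite(
            year=year,
            swir=np.zeros((2, 2)),
            masked_fraction=masked_fraction,
            n_scenes=3,
            has_swir=has_swir,
        )

    def test_clean_composites_all_kept(self):
        comps = [self._comp(y) for y in range(2000, 2005)]
        kept, report = filter_composites(comps, 0.0)
        assert len(kept) == 5
        assert report.empty

    def test_missing_band_dropped_with_reason(self):
        comps = [self._comp(2000 + i) for i in range(30)]
        comps[7] = self._comp(2007, has_swir=False)
        kept, report = filter_composites(comps, 0.0)
        assert len(kept) == 29
        assert report.iloc[0]["reason"] == "missing SWIR band"
        assert report.iloc[0]["year"] == 2007

    def test_strict_threshold(self):
        comps = [
            self._comp(2000, 0.0),
            self._comp(2001, 0.001),
            self._comp(2002, 0.2),
        ]
        kept, report = filter_composites(comps, 0.0)
        assert [c.year for c in kept] == [2000]
        assert len(report) == 2

    def test_kept_ordered_by_year(self):
        comps = [self._comp(y) for y in (2005, 2001, 2003)]
        kept, _ = filter_composites(comps)
        assert [c.year for c in kept] == [2001, 2003, 2005]
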