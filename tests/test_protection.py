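"""Protected-area overlap per range and per cell, and protection trends."""

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely import box

from riskgrid.geoio import StudyLayers, Taxon
from riskgrid.gridding import GridConfig, build_grid, presence_matrix
from riskgrid.hotspots import select_hotspots
from riskgrid.peripherality import DegenerateGeometryError
from riskgrid.protection import (
    cell_protection_table,
    protected_fraction_range,
    protection_vs_richness,
    protection_vs_time,
)

KM = 1_000.0


def _taxon(tid, geom, **kw):
    defaults = dict(name="", group="birds", national_status="threatened")
    defaults.update(kw)
    return Taxon(taxon_id=tid, focal_range=geom, **defaults)


class TestProtectedFractionRange:
    focal = box(0, 0, 1000 * KM, 1000 * KM)

    def test_fully_protected_region(self):
        layers = StudyLayers(self.focal, self.focal, [self.focal], [])
        t = _taxon("t", box(100 * KM, 100 * KM, 300 * KM, 300 * KM))
        assert protected_fraction_range(t, layers) == 1.0

    def test_no_protected_overlap(self):
        layers = StudyLayers(
            self.focal, self.focal, [box(900 * KM, 900 * KM, 950 * KM, 950 * KM)], []
        )
        t = _taxon("t", box(100 * KM, 100 * KM, 300 * KM, 300 * KM))
        assert protected_fraction_range(t, layers) == 0.0

    def test_quarter_protected_square_with_mc_oracle(self, rng):
        t_range = box(0, 0, 200 * KM, 200 * KM)
        pa = box(0, 0, 100 * KM, 100 * KM)
        layers = StudyLayers(self.focal, self.focal, [pa], [])
        t = _taxon("t", t_range)
        exact = protected_fraction_range(t, layers)
        assert exact == pytest.approx(0.25, rel=1e-12)
        n = 100_000
        xs = rng.uniform(0, 200 * KM, n)
        ys = rng.uniform(0, 200 * KM, n)
        mc = shapely.contains_xy(pa, xs, ys).mean()
        assert abs(mc - exact) < 0.01

    def test_invariant_to_splitting_protected_polygons(self):
        t = _taxon("t", box(0, 0, 200 * KM, 200 * KM))
        whole = StudyLayers(self.focal, self.focal, [box(0, 0, 100 * KM, 100 * KM)], [])
        split = StudyLayers(
            self.focal,
            self.focal,
            [box(0, 0, 50 * KM, 100 * KM), box(50 * KM, 0, 100 * KM, 100 * KM)],
            [],
        )
        assert protected_fraction_range(t, whole) == pytest.approx(
            protected_fraction_range(t, split), rel=1e-12
        )

    def test_range_outside_focal_rejected(self):
        layers = StudyLayers(self.focal, self.focal.buffer(2000 * KM), [], [])
        t = _taxon("t", box(1500 * KM, 0, 1600 * KM, 100 * KM))
        with pytest.raises(DegenerateGeometryError):
            protected_fraction_range(t, layers)


class TestCellProtection:
    def _fixture(self, protected):
        region = box(0, 0, 500 * KM, 300 * KM)
        grid = build_grid(region, protected, GridConfig(cell_size=100 * KM))
        taxa = [
            _taxon(f"t{i}", box(x, y, x + 150 * KM, y + 150 * KM),
                   global_status="vulnerable")
            for i, (x, y) in enumerate(
                np.random.default_rng(5).uniform(0, 300 * KM, size=(12, 2))
            )
        ]
        pm = presence_matrix(grid, taxa, region)
        ids = [t.taxon_id for t in taxa]
        hn = select_hotspots(pm.richness(ids), 0.2, cell_ids=pm.cell_ids, label="n")
        hg = select_hotspots(pm.richness(ids[:6]), 0.2, cell_ids=pm.cell_ids, label="g")
        return grid, pm, hn, hg, ids

    def test_no_protection_all_zero(self):
        grid, pm, hn, hg, ids = self._fixture(None)
        s = cell_protection_table(grid, pm, hn, hg, ids, ids)
        assert (s.table["protected_fraction"] == 0).all()
        assert s.landweighted_hotspot_national == 0.0

    def test_fully_protected_all_one(self):
        region = box(0, 0, 500 * KM, 300 * KM)
        grid, pm, hn, hg, ids = self._fixture([region])
        s = cell_protection_table(grid, pm, hn, hg, ids, ids)
        assert np.allclose(s.table["protected_fraction"], 1.0)
        assert s.landweighted_hotspot_national == pytest.approx(1.0)

    def test_landweighted_matches_recomputation(self, small_layers):
        grid = build_grid(small_layers.focal_region, small_layers.protected_areas)
        pm = presence_matrix(grid, small_layers.taxa, small_layers.focal_region)
        nat = [t.taxon_id for t in small_layers.taxa if t.nationally_at_risk]
        glob = [t.taxon_id for t in small_layers.taxa if t.globally_at_risk]
        hn = select_hotspots(pm.richness(nat), 0.05, cell_ids=pm.cell_ids, label="n")
        hg = select_hotspots(pm.richness(glob), 0.05, cell_ids=pm.cell_ids, label="g")
        s = cell_protection_table(grid, pm, hn, hg, nat, glob)
        mask = s.table["is_hotspot_national"].to_numpy()
        direct = (
            s.table["protected_area"].to_numpy()[mask].sum()
            / s.table["land_area"].to_numpy()[mask].sum()
        )
        assert s.landweighted_hotspot_national == pytest.approx(direct, rel=1e-12)

    def test_cell_protection_additivity(self, small_layers):
        # summed per-cell protected area equals area(protected ∩ region)
        grid = build_grid(small_layers.focal_region, small_layers.protected_areas)
        total = shapely.unary_union(small_layers.protected_areas).intersection(
            small_layers.focal_region
        ).area
        assert grid.protected_areas().sum() == pytest.approx(total, rel=1e-6)


def _cell_records(n, rng, slope=0.0, hotspot=False):
    richness = rng.integers(0, 15, size=n).astype(float)
    eta = -2.0 + slope * richness
    mu = 1 / (1 + np.exp(-eta))
    phi = 30.0
    pf = rng.beta(mu * phi, (1 - mu) * phi)
    return pd.DataFrame(
        {
            "protected_fraction": pf,
            "richness_national": richness,
            "is_hotspot_national": hotspot,
            "is_hotspot_global": False,
            "land_area": 1e10,
            "protected_area": pf * 1e10,
        }
    )


class TestProtectionVsRichness:
    def test_null_slope_within_3se(self, rng):
        hits = 0
        reps = 60
        for _ in range(reps):
            rec = _cell_records(300, rng)
            fit, trend = protection_vs_richness(rec, "national", False)
            j = fit.names.index("richness_national")
            se = np.sqrt(fit.vcov[j, j])
            hits += abs(fit.coefficients[j]) <= 3 * se
        assert hits / reps >= 0.9
        assert set(trend.columns) == {"richness", "fitted_protected_fraction"}

    def test_recovers_positive_slope(self, rng):
        rec = _cell_records(1000, rng, slope=0.1)
        fit, _ = protection_vs_richness(rec, "national", False)
        j = fit.names.index("richness_national")
        assert fit.coefficients[j] == pytest.approx(0.1, abs=0.03)

    def test_small_stratum_rejected(self, rng):
        rec = _cell_records(2, rng)
        with pytest.raises(ValueError, match="10"):
            protection_vs_richness(rec, "national", False)


class TestProtectionVsTime:
    def _metrics(self, n, rng, slope=0.0):
        years = rng.uniform(0, 40, n)
        mu = 1 / (1 + np.exp(-(-2.0 + slope * years)))
        phi = 25.0
        return pd.DataFrame(
            {
                "protected_fraction": rng.beta(mu * phi, (1 - mu) * phi),
                "years_since_assessment": years,
            }
        )

    def test_power_against_strong_trend(self, rng):
        rejections = 0
        for _ in range(25):
            _, lr = protection_vs_time(self._metrics(400, rng, slope=0.05))
            rejections += lr.p < 0.05
        assert rejections / 25 >= 0.8

    def test_constant_protection_singular(self, rng):
        m = self._metrics(50, rng)
        m["protected_fraction"] = 0.3
        with pytest.raises(ValueError, match="singular"):
            protection_vs_time(m)

    def test_all_years_missing_rejected(self):
        m = pd.DataFrame(
            {"protected_fraction": [0.1, 0.2], "years_since_assessment": [np.nan] * 2}
        )
        with pytest.raises(ValueError):
            protection_vs_time(m)
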