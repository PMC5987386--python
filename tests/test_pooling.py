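import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanobmd.bmd import BmdResult
from nanobmd.pooling import (
    PooledInterval,
    build_interval_table,
    check_published_medians,
    pool_endpoints,
    pool_intervals,
)
from nanobmd.reference import published_dose_intervals, published_pooled_medians


def _result(endpoint, bmdl, bmdu, status="ok", **kwargs):
    meta = dict(material_id="NM105", context_id="in_vivo_instillation",
                metric="ug_per_cm2", ces=0.2, confidence=0.9)
    meta.update(kwargs)
    ced = None if status == "no_response" else (bmdl + (bmdu or bmdl)) / 2
    return BmdResult(endpoint=endpoint, ced=ced, bmdl=bmdl, bmdu=bmdu,
                     status=status, **meta)


class TestPoolIntervals:
    def test_in_vivo_nm105_bmdu_median(self):
        """Median of the four in vivo NM105 upper bounds is 0.0755."""
        pairs = [(0.0011, 0.067), (0.00069, 0.13), (0.00019, 0.084),
                 (0.00075, 0.0091)]
        _, bmdu, n = pool_intervals(pairs)
        assert n == 4
        assert bmdu == pytest.approx(0.0755, abs=1e-6)

    def test_ali_nm105_bmdl_median(self):
        pairs = [(0.051, 0.80), (0.037, 0.81), (0.078, 0.83), (0.070, 0.82)]
        bmdl, _, _ = pool_intervals(pairs)
        assert bmdl == pytest.approx(0.0605, abs=1e-6)

    def test_single_endpoint_is_its_own_interval(self):
        bmdl, bmdu, n = pool_intervals([(0.5, 2.0)])
        assert (bmdl, bmdu, n) == (0.5, 2.0, 1)

    def test_nd_excluded_by_default(self):
        bmdl, _, n = pool_intervals([(0.53, 2.85), (None, None), (4.86, 10.47),
                                     (2.82, 6.36)])
        assert n == 3
        assert bmdl == pytest.approx(2.82)

    def test_nd_as_infinite_policy(self):
        bmdl, bmdu, n = pool_intervals(
            [(1.0, 2.0), (None, None), (3.0, 4.0), (5.0, 6.0)],
            nd_policy="infinite",
        )
        assert n == 3
        assert bmdl == pytest.approx(4.0)  # median of {1, 3, 5, inf}
        assert bmdu == pytest.approx(5.0)

    def test_all_nd_gives_none(self):
        bmdl, bmdu, n = pool_intervals([(None, None), (None, None)])
        assert bmdl is None and bmdu is None and n == 0

    @given(
        pairs=st.lists(
            st.tuples(
                st.floats(min_value=0.01, max_value=10.0),
                st.floats(min_value=10.0, max_value=100.0),
            ),
            min_size=1, max_size=6,
        ),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=60, deadline=None)
    def test_permutation_invariance_and_bounds(self, pairs, seed):
        bmdl, bmdu, _ = pool_intervals(pairs)
        rng = np.random.default_rng(seed)
        shuffled = [pairs[i] for i in rng.permutation(len(pairs))]
        assert pool_intervals(shuffled)[:2] == (bmdl, bmdu)
        lowers = [p[0] for p in pairs]
        uppers = [p[1] for p in pairs]
        assert min(lowers) <= bmdl <= max(lowers)
        assert min(uppers) <= bmdu <= max(uppers)
        assert bmdl <= bmdu


class TestPoolEndpoints:
    def test_unbounded_upper_enters_as_infinity(self):
        results = [
            _result("IL-1b", 1.0, 2.0),
            _result("IL-6", 3.0, None, status="unbounded_upper"),
        ]
        pooled = pool_endpoints(results)
        assert pooled.n_defined == 2
        assert pooled.bmdl_median == pytest.approx(2.0)
        assert math.isinf(pooled.bmdu_median)

    def test_no_response_counts_as_nd(self):
        results = [_result("IL-1b", 1.0, 2.0),
                   _result("IL-6", None, None, status="no_response")]
        pooled = pool_endpoints(results)
        assert pooled.n_defined == 1
        assert pooled.bmdl_median == pytest.approx(1.0)

    def test_mixed_cells_rejected(self):
        with pytest.raises(ValueError, match="mix"):
            pool_endpoints([
                _result("IL-1b", 1.0, 2.0),
                _result("IL-6", 1.0, 2.0, material_id="NM100"),
            ])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool_endpoints([])


class TestIntervalTable:
    def test_grid_shape(self):
        results = [
            _result(ep, 1.0, 2.0, material_id=m, context_id=c)
            for m in ("NM105", "NM100")
            for c in ("in_vivo_instillation", "ali_insert_3h21h")
            for ep in ("IL-1b", "IL-6")
        ]
        grid = build_interval_table(results, "ug_per_cm2")
        assert grid.shape == (2, 2)
        assert isinstance(grid.iloc[0, 0], PooledInterval)

    def test_empty_input(self):
        assert build_interval_table([], "ug_per_cm2").empty


class TestPublishedMedians:
    @pytest.fixture(scope="class")
    def report(self):
        return check_published_medians(
            published_dose_intervals(), published_pooled_medians()
        ).set_index(["context_id", "material_id"])

    def test_verifiable_cells_reproduce(self, report):
        for key in [
            ("in_vivo_instillation", "NM105"),
            ("in_vivo_instillation", "NM101"),
            ("in_vivo_instillation", "NM212"),
            ("ali_insert_3h21h", "NM105"),
            ("ali_insert_3h21h", "NM101"),
            ("ali_insert_3h21h", "NM100"),
            ("submerged_insert_3h21h", "NM105"),
            ("submerged_insert_3h21h", "NM101"),
            ("submerged_insert_3h21h", "NM212"),
            ("submerged_plate_24h", "NM101"),
            ("submerged_plate_24h", "NM100"),
            ("submerged_plate_24h", "NM212"),
        ]:
            assert report.loc[key, "consistent"], key

    def test_all_nd_cell_is_consistent(self, report):
        assert report.loc[("in_vivo_instillation", "NM100"), "consistent"]

    def test_discrepant_cells_flagged(self, report):
        """Cells that do not follow the exclude-ND median rule are reported."""
        for key in [
            ("submerged_plate_24h", "NM105"),
            ("ali_insert_3h21h", "NM212"),
            ("submerged_insert_3h21h", "NM100"),
        ]:
            assert not report.loc[key, "consistent"], key
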