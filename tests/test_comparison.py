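import math

import pytest

from nanobmd.comparison import (
    apply_metric_views,
    fold_difference,
    loael_fold_table,
    rank_materials,
)
from nanobmd.dose_metrics import DoseQuantity
from nanobmd.pooling import PooledInterval


def _interval(material, bmdl, bmdu, context="in_vivo_instillation",
              metric="ug_per_cm2"):
    defined = bmdl is not None
    return PooledInterval(
        material_id=material, context_id=context, metric=metric,
        bmdl_median=bmdl, bmdu_median=bmdu,
        endpoints_used=["IL-1b"], n_defined=4 if defined else 0,
    )


class TestFoldDifference:
    def test_ali_vs_in_vivo(self):
        fold = fold_difference(
            DoseQuantity(1.0, "ug_per_cm2", "ali_insert_3h21h"),
            DoseQuantity(0.1, "ug_per_cm2", "in_vivo_instillation"),
        )
        assert fold == pytest.approx(10.0)

    def test_plates_vs_in_vivo(self):
        fold = fold_difference(
            DoseQuantity(10.0, "ug_per_cm2", "submerged_plate_24h"),
            DoseQuantity(0.1, "ug_per_cm2", "in_vivo_instillation"),
        )
        assert fold == pytest.approx(100.0)

    def test_identity_and_reciprocal(self):
        a = DoseQuantity(3.0, "ug_per_cm2", "ali_insert_3h21h")
        b = DoseQuantity(0.7, "ug_per_cm2", "in_vivo_instillation")
        assert fold_difference(a, a) == 1.0
        assert fold_difference(a, b) * fold_difference(b, a) == pytest.approx(1.0)

    def test_metric_mismatch(self):
        with pytest.raises(ValueError, match="metric"):
            fold_difference(
                DoseQuantity(1.0, "ug_per_cm2", "ali_insert_3h21h"),
                DoseQuantity(1.0, "ug_per_lungs", "in_vivo_instillation"),
            )

    def test_undefined_operand_flagged(self):
        table = loael_fold_table(
            {"in_vivo_instillation": 0.1, "ali_insert_3h21h": None},
            "ug_per_cm2",
        )
        row = table.set_index("context_id").loc["ali_insert_3h21h"]
        assert not row["defined"] and math.isnan(row["fold_vs_reference"])


class TestRanking:
    def test_disjoint_intervals_ordered(self):
        ranking = rank_materials([_interval("B", 5.0, 6.0), _interval("A", 1.0, 2.0)])
        assert ranking.order == ["A", "B"]
        assert ranking.tie_groups == [["A"], ["B"]]

    def test_overlapping_intervals_tie(self):
        ranking = rank_materials([_interval("A", 1.0, 4.0), _interval("B", 3.0, 6.0)])
        assert ranking.tie_groups == [["A", "B"]]

    def test_nd_last_never_interleaved(self):
        ranking = rank_materials(
            [_interval("A", 1.0, 2.0), _interval("X", None, None),
             _interval("B", 5.0, 6.0)]
        )
        assert ranking.order == ["A", "B", "X"]
        assert ranking.nd_materials == ["X"]

    def test_three_grouped_above_nd(self):
        """Defined materials with overlapping intervals group above an ND one."""
        ranking = rank_materials(
            [_interval("NM105", 0.0007, 0.075), _interval("NM101", 0.0022, 0.084),
             _interval("NM212", 0.0000, 0.074), _interval("NM100", None, None)]
        )
        assert ranking.tie_groups == [["NM212", "NM105", "NM101"]]
        assert ranking.order[-1] == "NM100"

    def test_uniform_rescale_cannot_reorder(self):
        pooled = [_interval("A", 1.0, 2.0), _interval("B", 2.5, 6.0),
                  _interval("C", 10.0, 20.0)]
        base = rank_materials(pooled)
        scaled = rank_materials(
            [_interval(p.material_id, 7.0 * p.bmdl_median, 7.0 * p.bmdu_median)
             for p in pooled]
        )
        assert scaled.order == base.order
        assert scaled.tie_groups == base.tie_groups

    def test_needs_two_materials(self):
        with pytest.raises(ValueError):
            rank_materials([_interval("A", 1.0, 2.0)])


class TestMetricViews:
    def test_identity_view(self, materials, contexts):
        views = apply_metric_views([_interval("NM105", 0.01, 0.08)],
                                   materials, contexts)
        row = views[views.view == "ug_per_cm2"].iloc[0]
        assert (row.bmdl, row.bmdu) == (0.01, 0.08)

    def test_per_macrophage_view(self, materials, contexts):
        views = apply_metric_views([_interval("NM105", 0.01, 0.08)],
                                   materials, contexts)
        row = views[views.view == "ug_per_1e6_macrophages"].iloc[0]
        # in vivo: ug/cm^2 * 4000 cm^2 / 25e6 macrophages * 1e6
        assert row.bmdl == pytest.approx(0.01 * 4000 / 25)

    def test_primary_view_uses_bet(self, materials, contexts):
        views = apply_metric_views([_interval("NM101", 0.01, 0.08)],
                                   materials, contexts)
        row = views[views.view == "cm2_per_1e6_macrophages_primary"].iloc[0]
        assert row.bmdl == pytest.approx(0.01 * 160 * 316 * 0.01, rel=1e-9)

    def test_agglomerate_view_matches_route_medium(self, materials, contexts):
        ali = apply_metric_views(
            [_interval("NM212", 1.0, 2.0, context="ali_insert_3h21h")],
            materials, contexts,
        )
        row = ali[ali.view == "cm2_per_1e6_macrophages_agglomerate"].iloc[0]
        # ALI: aerosol agglomerates (27.27 m^2/g), 60,000 macrophages/cm^2
        per_mac = 1.0 / 0.06
        assert row.bmdl == pytest.approx(per_mac * (6000 / (1.1 * 200)) * 0.01,
                                         rel=1e-9)

    def test_bet_normalisation_can_reorder(self, materials, contexts):
        """Equally potent mass intervals separate under BET normalisation.

        The hydrophobically coated material has a far higher primary surface
        area, so its surface-area-normalised interval moves up and it ranks
        as less surface-reactive.
        """
        pooled = [_interval("NM105", 1.0, 2.0), _interval("NM101", 1.0, 2.0)]
        assert rank_materials(pooled).tie_groups == [["NM105", "NM101"]]
        views = apply_metric_views(pooled, materials, contexts)
        bet = views[views.view == "cm2_per_1e6_macrophages_primary"]
        converted = [
            _interval(r.material_id, r.bmdl, r.bmdu, metric="cm2_per_1e6_macrophages")
            for r in bet.itertuples()
        ]
        ranking = rank_materials(converted)
        assert ranking.order == ["NM105", "NM101"]
        assert ranking.tie_groups == [["NM105"], ["NM101"]]

    def test_nd_cells_flagged(self, materials, contexts):
        views = apply_metric_views([_interval("NM105", None, None)],
                                   materials, contexts)
        assert (views.flag == "ND").all()
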