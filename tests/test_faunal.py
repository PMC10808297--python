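import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from microfoodweb.faunal import (
    FaunalWeights,
    channel_index,
    classify_quadrant,
    enrichment_structure_basal,
    faunal_index_table,
    guild_components,
    maturity_indices,
    trophic_diversity,
)

# convenient fixture genera per guild
BA1 = "Rhabditis"
BA2 = "Acrobeloides"
FU2 = "Filenchus"
PP3 = "Helicotylenchus"
OM4 = "Eudorylaimus"
OM5 = "Aporcelaimellus"
CA4 = "Mononchus"


class TestGuildComponents:
    def test_ba1_ba2_mixture(self, annotated_factory):
        ann = annotated_factory({BA1: 50, BA2: 50})
        c = guild_components(ann, "S1")
        assert (c.e, c.b, c.s) == (160.0, 40.0, 0.0)

    def test_fu2_feeds_enrichment_and_basal(self, annotated_factory):
        ann = annotated_factory({FU2: 10})
        c = guild_components(ann, "S1")
        assert (c.e, c.b, c.s) == (8.0, 8.0, 0.0)

    def test_structure_weights_by_cp(self, annotated_factory):
        ann = annotated_factory({PP3: 5, OM4: 10, OM5: 2, CA4: 3})
        c = guild_components(ann, "S1")
        # PP excluded; Om4 and Ca4 weighted alike; cp5 weight 5.0
        assert c.s == pytest.approx(3.2 * 13 + 5.0 * 2)
        assert c.e == 0.0 and c.b == 0.0

    def test_no_free_living_taxa_gives_zero_components(self, annotated_factory):
        ann = annotated_factory({PP3: 50})
        c = guild_components(ann, "S1")
        assert (c.e, c.b, c.s) == (0.0, 0.0, 0.0)


class TestEnrichmentStructureBasal:
    def test_hand_evaluated_percentages(self, annotated_factory):
        ann = annotated_factory({BA1: 50, BA2: 50})
        ei, si, bi = enrichment_structure_basal(guild_components(ann, "S1"))
        assert (ei, si, bi) == (80.0, 0.0, 20.0)

    def test_pure_ba1_boundary(self, annotated_factory):
        ann = annotated_factory({BA1: 30})
        ei, si, bi = enrichment_structure_basal(guild_components(ann, "S1"))
        assert ei == 100.0 and math.isnan(si) and bi == 0.0

    def test_all_zero_components_all_undefined(self, annotated_factory):
        ann = annotated_factory({PP3: 10})
        ei, si, bi = enrichment_structure_basal(guild_components(ann, "S1"))
        assert math.isnan(ei) and math.isnan(si) and math.isnan(bi)


class TestChannelIndex:
    def test_mixed_channels(self, annotated_factory):
        ann = annotated_factory({BA1: 10, FU2: 10})
        assert channel_index(guild_components(ann, "S1")) == pytest.approx(20.0)

    def test_pure_fungal_and_pure_bacterial(self, annotated_factory):
        assert channel_index(
            guild_components(annotated_factory({FU2: 7}), "S1")
        ) == pytest.approx(100.0, abs=1e-12)
        assert channel_index(
            guild_components(annotated_factory({BA1: 7}), "S1")
        ) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_without_opportunists(self, annotated_factory):
        ann = annotated_factory({OM4: 5})
        assert math.isnan(channel_index(guild_components(ann, "S1")))


class TestMaturityIndices:
    def test_weighted_mean_cp(self, annotated_factory):
        ann = annotated_factory({BA2: 3, OM4: 1})  # cp2 x3 + cp4 x1
        mi, ppi, ratio = maturity_indices(ann, "S1")
        assert mi == pytest.approx(2.5)
        assert math.isnan(ppi) and math.isnan(ratio)

    def test_single_pp_taxon(self, annotated_factory):
        ann = annotated_factory({PP3: 8, BA2: 8})
        mi, ppi, ratio = maturity_indices(ann, "S1")
        assert ppi == 3.0
        assert ratio == pytest.approx(3.0 / 2.0)

    def test_cp1_exclusion_option(self, annotated_factory):
        ann = annotated_factory({BA1: 10, BA2: 10})
        mi_with, _, _ = maturity_indices(ann, "S1", include_cp1=True)
        mi_without, _, _ = maturity_indices(ann, "S1", include_cp1=False)
        assert mi_with == pytest.approx(1.5)
        assert mi_without == pytest.approx(2.0)

    def test_mi_bounded_by_cp_range(self, annotated_factory, rng):
        genera = [BA1, BA2, FU2, OM4, OM5]
        cps = [1, 2, 2, 4, 5]
        for _ in range(200):
            counts = dict(zip(genera, rng.integers(0, 20, size=5)))
            if sum(counts.values()) == 0:
                continue
            ann = annotated_factory({g: float(v) for g, v in counts.items()})
            mi, _, _ = maturity_indices(ann, "S1")
            present = [cp for g, cp in zip(genera, cps) if counts[g] > 0]
            assert min(present) <= mi <= max(present)


class TestTrophicDiversity:
    @pytest.mark.parametrize(
        "groups,expected",
        [([5, 5, 5, 5], 4.0), ([9, 0, 0, 0], 1.0), ([0.5, 0.5, 0, 0], 2.0)],
    )
    def test_reciprocal_simpson(self, groups, expected):
        assert trophic_diversity(groups) == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            trophic_diversity([0, 0, 0, 0])


class TestQuadrants:
    @pytest.mark.parametrize(
        "ei,si,quadrant",
        [(60, 40, "A"), (40, 60, "C"), (50, 50, "B"), (10, 10, "D"), (90, 90, "B")],
    )
    def test_classification(self, ei, si, quadrant):
        assert classify_quadrant(ei, si) == quadrant

    def test_undefined_inputs_give_none(self):
        assert classify_quadrant(float("nan"), 50.0) is None

    @given(
        st.floats(min_value=0, max_value=100, allow_nan=False),
        st.floats(min_value=0, max_value=100, allow_nan=False),
    )
    def test_partition_exactly_one_label(self, ei, si):
        assert classify_quadrant(ei, si) in {"A", "B", "C", "D"}


class TestIndexProperties:
    @given(st.lists(st.integers(min_value=0, max_value=200), min_size=7, max_size=7))
    def test_percentage_indices_in_range(self, annotated_factory, counts):
        genera = [BA1, BA2, FU2, PP3, OM4, OM5, CA4]
        ann = annotated_factory(dict(zip(genera, map(float, counts))))
        c = guild_components(ann, "S1")
        for value in (*enrichment_structure_basal(c), channel_index(c)):
            assert math.isnan(value) or 0.0 <= value <= 100.0

    def test_ei_scale_invariant(self, annotated_factory):
        small = annotated_factory({BA1: 3, BA2: 5, FU2: 7})
        big = annotated_factory({BA1: 30, BA2: 50, FU2: 70})
        ei_s, *_ = enrichment_structure_basal(guild_components(small, "S1"))
        ei_b, *_ = enrichment_structure_basal(guild_components(big, "S1"))
        assert ei_s == pytest.approx(ei_b, abs=1e-12)

    def test_adding_ba1_never_decreases_ei(self, annotated_factory):
        previous = -1.0
        for ba1 in [1, 5, 20, 100, 400]:
            ann = annotated_factory({BA1: float(ba1), BA2: 50, FU2: 10})
            ei, *_ = enrichment_structure_basal(guild_components(ann, "S1"))
            assert ei >= previous
            previous = ei

    def test_adding_omnivores_never_decreases_si(self, annotated_factory):
        previous = -1.0
        for om in [0, 2, 10, 50, 200]:
            ann = annotated_factory({BA2: 40, FU2: 10, OM4: float(om)})
            _, si, _ = enrichment_structure_basal(guild_components(ann, "S1"))
            assert si >= previous
            previous = si


class TestFaunalIndexTable:
    def test_columns_and_na_handling(self, annotated_factory):
        ann = annotated_factory({BA1: [10, 0], PP3: [0, 5]})
        out = faunal_index_table(ann)
        assert list(out.columns) == [
            "EI", "SI", "BI", "CI", "TD", "MI", "PPI", "PPI_MI", "quadrant",
        ]
        assert out.loc["S1", "EI"] == 100.0
        # PP-only sample: enrichment machinery undefined, PPI defined
        assert math.isnan(out.loc["S2", "EI"])
        assert out.loc["S2", "PPI"] == 3.0
        assert out.loc["S2", "quadrant"] is None

    def test_custom_weights_override(self, annotated_factory, tmp_path):
        cfg = tmp_path / "w.yaml"
        cfg.write_text("enrichment:\n  Ba1: 1.0\n  Fu2: 1.0\nbasal:\n  Ba2: 1.0\n")
        weights = FaunalWeights.from_yaml(cfg)
        ann = annotated_factory({BA1: 10, BA2: 10})
        out = faunal_index_table(ann, weights=weights)
        assert out.loc["S1", "EI"] == pytest.approx(50.0)
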