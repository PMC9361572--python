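import math
import random

import pytest

from ksdater import (
    APIACEAE_RATE,
    CELERY_ANCHORS,
    DICOT_RATE,
    EventAnchorSet,
    RateModel,
    assign_event,
    bin_pairs,
    divergence_time,
    select_rate,
)


class TestDivergenceTime:
    def test_zero_ks_is_time_zero(self):
        assert divergence_time(0.0, APIACEAE_RATE).T == 0.0

    def test_apiaceae_minimum_endpoint(self):
        # smallest celery-coriander ortholog Ks at the within-Apiaceae rate
        t = divergence_time(0.1103, RateModel("apiaceae", 5.2e-9))
        assert round(t.T, 2) == 10.61

    def test_dicot_minimum_endpoint(self):
        # smallest celery-Arabidopsis ortholog Ks at the dicot rate
        t = divergence_time(1.3407, RateModel("dicot", 1.5e-8))
        assert round(t.T, 2) == 44.69

    def test_negative_ks_rejected(self):
        with pytest.raises(ValueError):
            divergence_time(-0.1, APIACEAE_RATE)

    def test_nan_propagates(self):
        assert math.isnan(divergence_time(math.nan, APIACEAE_RATE).T)

    @pytest.mark.parametrize("ks", [0.05, 0.3, 1.2])
    def test_linear_in_ks(self, ks):
        t1 = divergence_time(ks, APIACEAE_RATE).T
        t2 = divergence_time(2 * ks, APIACEAE_RATE).T
        assert t2 == pytest.approx(2 * t1)

    def test_halves_when_rate_doubles(self):
        slow = RateModel("slow", 5e-9)
        fast = RateModel("fast", 1e-8)
        assert divergence_time(0.4, slow).T == pytest.approx(
            2 * divergence_time(0.4, fast).T
        )


class TestSelectRate:
    def test_within_apiaceae(self):
        assert select_rate("celery", "coriander").r == 5.2e-9

    def test_cross_clade(self):
        assert select_rate("celery", "arabidopsis").r == 1.5e-8

    def test_unknown_species_rejected(self):
        with pytest.raises(KeyError):
            select_rate("celery", "unknown_sp")


class TestAnchorSet:
    def test_non_increasing_anchors_rejected(self):
        with pytest.raises(ValueError):
            EventAnchorSet("x", (("a", 0.5), ("b", 0.4)))

    def test_duplicate_event_names_rejected(self):
        with pytest.raises(ValueError):
            EventAnchorSet("x", (("a", 0.1), ("a", 0.2)))

    def test_interval_labels_cover_all_regions(self):
        labels = CELERY_ANCHORS.interval_labels()
        assert labels[0] == "after_alpha"
        assert labels[-1] == "before_gamma"
        assert len(labels) == 4


class TestAssignEvent:
    def test_green_interval_attributed_to_celery_omega(self):
        asg = assign_event(0.6081, CELERY_ANCHORS)
        assert asg.interval_label == "between_alpha_celery-omega"
        assert asg.attributed_event == "celery-omega"
        assert asg.color_class == "green"

    def test_orange_interval_attributed_to_gamma(self):
        asg = assign_event(0.9464, CELERY_ANCHORS)
        assert asg.interval_label == "between_celery-omega_gamma"
        assert asg.attributed_event == "gamma"
        assert asg.color_class == "orange"

    def test_above_largest_anchor_unattributed(self):
        asg = assign_event(1.5, CELERY_ANCHORS)
        assert asg.interval_label == "before_gamma"
        assert asg.attributed_event is None
        assert asg.color_class == "blue"

    def test_below_smallest_anchor_is_youngest(self):
        asg = assign_event(0.1, CELERY_ANCHORS)
        assert asg.interval_label == "after_alpha"
        assert asg.attributed_event == "alpha"
        assert asg.color_class == "red"

    def test_ks_exactly_at_anchor_belongs_to_that_event(self):
        assert assign_event(0.3659, CELERY_ANCHORS).attributed_event == "alpha"

    def test_nan_unassigned_with_warning(self, caplog):
        asg = assign_event(math.nan, CELERY_ANCHORS, pair_id="p")
        assert asg.interval_label == "unassigned"
        assert asg.attributed_event is None


class TestBinPairs:
    def test_published_celery_paralogs_split_two_and_two(self):
        ks_values = [
            ("AgBZR1.1-AgBZR1.8", 0.6081),
            ("AgBZR1.3-AgBZR1.5", 0.6067),
            ("AgBZR1.2-AgBZR1.3", 0.9464),
            ("AgBZR1.2-AgBZR1.5", 0.9687),
        ]
        _, counts = bin_pairs(ks_values, CELERY_ANCHORS)
        assert counts["between_alpha_celery-omega"] == 2
        assert counts["between_celery-omega_gamma"] == 2
        assert counts["after_alpha"] == 0 and counts["before_gamma"] == 0

    def test_empty_input_gives_zero_counts(self):
        assignments, counts = bin_pairs([], CELERY_ANCHORS)
        assert assignments == []
        assert all(c == 0 for c in counts.values())

    def test_partition_property_against_brute_force(self):
        # every finite ks falls in exactly one interval, matching a
        # direct comparison against the bin edges
        rng = random.Random(0)
        anchors = CELERY_ANCHORS
        edges = [k for _, k in anchors.anchors]
        labels = anchors.interval_labels()
        ks_values = [rng.uniform(0, 2.0) for _ in range(10_000)] + list(edges)
        assignments, counts = bin_pairs(
            [(f"p{i}", ks) for i, ks in enumerate(ks_values)], anchors
        )
        assert sum(counts[l] for l in labels) == len(ks_values)
        for asg in assignments:
            idx = sum(1 for e in edges if asg.ks > e)  # brute-force bin index
            assert asg.interval_label == labels[idx]
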