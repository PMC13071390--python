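"""Quantification, saturation, harmonization and Mscore integration."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from repurscore import (
    ConfigurationError,
    Direction,
    EvidenceItem,
    EvidenceStream,
    HarmonizedPair,
    Modality,
    QuantPair,
    SaturationSpec,
    ValidationError,
    harmonize,
    integrate,
    quantify,
    saturate,
)
from repurscore.evidence_model import register_quantifier, _default_quantify


def _stream(sid="s", modality=Modality.GENOMICS, scale=1.0):
    return EvidenceStream(sid, sid, modality, SaturationSpec("tanh", scale))


def _item(sid="s", direction="supporting", magnitude=1.0, **payload):
    return EvidenceItem(sid, "T0", direction, magnitude, payload)


class TestQuantify:
    def test_empty_items_give_zero_pair(self):
        q = quantify([], _stream())
        assert (q.q_supporting, q.q_opposing) == (0.0, 0.0)

    def test_directional_magnitude_sums(self):
        items = [_item(magnitude=1.0)] * 3 + [_item(direction="opposing", magnitude=0.5)]
        q = quantify(items, _stream())
        assert (q.q_supporting, q.q_opposing) == (3.0, 0.5)

    def test_novelty_counts_only_recent_publications(self):
        # filter-then-sum oracle: years {2010, 2023, 2024}, cutoff 2020 -> 2
        items = [_item("lit", year=y) for y in (2010, 2023, 2024)]
        stream = _stream("lit", Modality.LITERATURE_NOVELTY)
        q = quantify(items, stream, novelty_year_cutoff=2020)
        assert (q.q_supporting, q.q_opposing) == (2.0, 0.0)
        overall = quantify(items, _stream("lit", Modality.LITERATURE_OVERALL))
        assert overall.q_supporting == 3.0

    def test_wrong_stream_id_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            quantify([_item("other")], _stream("s"))

    def test_negative_magnitude_is_validation_error(self):
        with pytest.raises(ValidationError):
            _item(magnitude=-1.0)

    def test_custom_quantifier_is_pluggable(self):
        count_pubs = lambda items, stream, cutoff: QuantPair(
            stream.stream_id, float(len(items)), 0.0
        )
        register_quantifier(Modality.CUSTOM, count_pubs)
        try:
            stream = _stream("c", Modality.CUSTOM)
            q = quantify([_item("c", magnitude=9.0)] * 4, stream)
            assert (q.q_supporting, q.q_opposing) == (4.0, 0.0)
        finally:
            register_quantifier(Modality.CUSTOM, _default_quantify)


class TestSaturate:
    @pytest.mark.parametrize("family", ["tanh", "hard_clip", "logistic_symmetric"])
    def test_zero_maps_to_zero(self, family):
        assert saturate(0.0, SaturationSpec(family, 3.0)) == 0.0

    def test_tanh_reference_value(self):
        assert saturate(2.0, SaturationSpec("tanh", 2.0)) == pytest.approx(
            math.tanh(1.0), abs=1e-12
        )

    def test_hard_clip_reaches_bound(self):
        assert saturate(10.0, SaturationSpec("hard_clip", 2.0)) == 1.0

    def test_logistic_symmetric_closed_form(self):
        q, scale = 1.7, 0.8
        expected = 2 / (1 + math.exp(-q / scale)) - 1
        assert saturate(q, SaturationSpec("logistic_symmetric", scale)) == pytest.approx(
            expected, abs=1e-15
        )

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            saturate(-0.1, SaturationSpec())

    @given(
        q=st.floats(0, 1e6),
        scale=st.floats(1e-3, 1e3),
        family=st.sampled_from(["tanh", "hard_clip", "logistic_symmetric"]),
    )
    def test_bounded_and_monotone(self, q, scale, family):
        spec = SaturationSpec(family, scale)
        g = saturate(q, spec)
        assert 0.0 <= g <= 1.0
        assert saturate(q + 1.0, spec) >= g


class TestHarmonize:
    def test_zero_pair_maps_to_zero(self):
        h = harmonize(QuantPair("s", 0, 0), SaturationSpec())
        assert (h.h_supporting, h.h_opposing, h.h_net) == (0, 0, 0)

    def test_saturation_skews_support_opposition_ratio(self):
        # raw 100:5 support-to-opposition harmonizes to near-parity
        h = harmonize(QuantPair("s", 100, 5), SaturationSpec("tanh", 1.0))
        assert h.h_supporting == pytest.approx(1.0, abs=1e-6)
        assert h.h_opposing == pytest.approx(math.tanh(5.0), abs=1e-12)
        assert 0 < h.h_net < 1e-4

    @given(a=st.floats(0, 1e3))
    def test_symmetric_pair_nets_to_zero(self, a):
        h = harmonize(QuantPair("s", a, a), SaturationSpec("tanh", 2.0))
        assert h.h_net == 0.0

    @given(
        qs=st.floats(0, 1e4), qo=st.floats(0, 1e4),
        family=st.sampled_from(["tanh", "hard_clip", "logistic_symmetric"]),
    )
    def test_net_in_unit_interval_and_sign_consistent(self, qs, qo, family):
        h = harmonize(QuantPair("s", qs, qo), SaturationSpec(family, 1.5))
        assert abs(h.h_net) <= 1.0
        if family != "hard_clip" and qs != qo:
            assert math.copysign(1, h.h_net) == math.copysign(1, qs - qo) or h.h_net == 0


class TestIntegrate:
    W = {"a": 0.3, "b": 0.2, "c": 0.2, "d": 0.15, "e": 0.15}

    @staticmethod
    def _pairs(nets):
        # encode desired h_net as pure supporting or opposing component
        return {
            s: HarmonizedPair(s, max(v, 0.0), max(-v, 0.0))
            for s, v in nets.items()
        }

    def test_zero_evidence_gives_zero_mscore(self):
        res = integrate(self._pairs({s: 0.0 for s in self.W}), self.W)
        assert res.mscore == 0.0

    def test_unit_weights_plain_sum(self):
        nets = dict(zip("abcde", [0.5, -0.2, 0.8, 0.1, 0.4]))
        res = integrate(self._pairs(nets), {s: 1.0 for s in nets})
        assert res.mscore == pytest.approx(1.6, abs=1e-12)

    def test_weighted_sum_hand_computed(self):
        nets = dict(zip("abcde", [0.5, -0.2, 0.8, 0.1, 0.4]))
        res = integrate(self._pairs(nets), self.W)
        # 0.3*0.5 - 0.2*0.2 + 0.2*0.8 + 0.15*0.1 + 0.15*0.4
        assert res.mscore == pytest.approx(0.345, abs=1e-12)
        assert sum(res.contributions.values()) == pytest.approx(res.mscore, abs=1e-12)

    def test_absent_stream_counts_as_zero_pair(self):
        res = integrate(self._pairs({"a": 0.5}), self.W)
        assert res.mscore == pytest.approx(0.15, abs=1e-12)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValidationError):
            integrate(self._pairs({"a": 0.5}), {"a": -1.0})

    def test_harmonized_stream_missing_from_weights_is_config_error(self):
        with pytest.raises(ConfigurationError):
            integrate(self._pairs({"zz": 0.5}), self.W)

    @given(st.lists(st.floats(-1, 1), min_size=1, max_size=5))
    def test_conservation_and_boundedness(self, nets_list):
        nets = {f"s{i}": v for i, v in enumerate(nets_list)}
        weights = {s: 1.0 for s in nets}
        res = integrate(self._pairs(nets), weights)
        assert res.mscore == pytest.approx(
            res.supporting_total - res.opposing_total, abs=1e-12
        )
        assert abs(res.mscore) <= sum(weights.values()) + 1e-12


def test_adding_supporting_evidence_never_decreases_mscore(streams):
    """Monotonicity under strictly increasing saturation."""
    from conftest import TARGETS
    from repurscore import score_association

    rng = np.random.default_rng(11)
    base = [
        EvidenceItem("genomics", "T0", "supporting", float(rng.uniform(0, 2)))
        for _ in range(5)
    ]
    a0 = score_association("M", TARGETS, "I", base, streams)
    a_sup = score_association(
        "M", TARGETS, "I",
        base + [EvidenceItem("genomics", "T1", "supporting", 0.7)], streams,
    )
    a_opp = score_association(
        "M", TARGETS, "I",
        base + [EvidenceItem("genomics", "T1", "opposing", 0.7)], streams,
    )
    assert a_sup.mscore >= a0.mscore
    assert a_opp.mscore <= a0.mscore


def test_zero_weight_stream_equals_absent_stream(streams):
    """Toggling semantics: weight 0 behaves exactly like no such stream."""
    from conftest import TARGETS
    from repurscore import score_association

    items = [
        EvidenceItem("genomics", "T0", "supporting", 2.0),
        EvidenceItem("transcriptomics", "T1", "opposing", 1.0,
                     {"effect_size": -1.0, "p_value": 0.01}),
    ]
    weights = {s: st.default_weight for s, st in streams.items()}
    weights["transcriptomics"] = 0.0
    with_zero = score_association("M", TARGETS, "I", items, streams, weights)

    reduced_streams = {s: v for s, v in streams.items() if s != "transcriptomics"}
    reduced_weights = {s: w for s, w in weights.items() if s != "transcriptomics"}
    without = score_association(
        "M", TARGETS, "I", [items[0]], reduced_streams, reduced_weights
    )
    assert with_zero.mscore == pytest.approx(without.mscore, abs=1e-15)


def test_brute_force_mscore_recomputation(streams):
    """Oracle: recompute Mscore from raw items without the pipeline types."""
    import math as m

    from conftest import random_association

    rng = np.random.default_rng(23)
    for _ in range(25):
        a = random_association(rng, streams, n_items=20)
        expected = 0.0
        for sid, stream in streams.items():
            if stream.modality is Modality.LITERATURE_NOVELTY:
                pool = [i for i in a.items
                        if i.stream_id == "literature_overall"
                        and i.payload["year"] >= 2021]
            else:
                pool = [i for i in a.items if i.stream_id == sid]
            qs = sum(i.magnitude for i in pool if i.direction is Direction.SUPPORTING)
            qo = sum(i.magnitude for i in pool if i.direction is Direction.OPPOSING)
            expected += stream.default_weight * (
                m.tanh(qs / stream.saturation.scale)
                - m.tanh(qo / stream.saturation.scale)
            )
        assert a.mscore == pytest.approx(expected, abs=1e-12)
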