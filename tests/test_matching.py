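"""Ontology element matching: the three cases, metrics and the sweep."""

import pytest

from ontoqa import fixtures as fx
from ontoqa import matching
from ontoqa.ontology import subtree_elements
from ontoqa.recognition import RecognizedEntity


def ent(text, label):
    return RecognizedEntity(0, max(1, len(text.split())), text, label)


class TestMatchEntity:
    def test_near_miss_resolves_within_upper_subtree(self, model, graph, fixture):
        m = matching.match_entity(ent("spectra score", "data collection"),
                                  model, graph, fixture.data)
        assert m.element == fx.iri("spectral count")
        assert m.provenance in ("single", "context_ranked")

    def test_exact_class_name_is_single_candidate(self, model, graph, fixture):
        m = matching.match_entity(ent("drug concentration", "parameter"),
                                  model, graph, fixture.data)
        assert m.element == fx.iri("drug concentration")
        assert m.provenance == "single"

    def test_instance_fallback_finds_typing_class(self, model, graph, fixture):
        m = matching.match_entity(ent("protein phosphate", "parameter"),
                                  model, graph, fixture.data)
        assert m.element == fx.iri("gene function")
        assert m.provenance == "instance"

    def test_comment_field_supports_match(self, model, graph, fixture):
        # "Neomycin resistance" appears only in the class comment
        m = matching.match_entity(ent("Neomycin resistance", "data collection"),
                                  model, graph, fixture.data)
        assert m.element == fx.iri("drug resistance")

    def test_unmatched_entity_reported_not_raised(self, model, graph, fixture):
        m = matching.match_entity(ent("zzzz qqqq", "instrument"),
                                  model, graph, fixture.data)
        assert m.element is None and m.provenance == "unmatched"

    def test_schema_match_stays_inside_subtree(self, model, graph, fixture):
        for text, label in [("spectra score", "data collection"),
                            ("genes", "material"),
                            ("pathways", "pathway element")]:
            m = matching.match_entity(ent(text, label), model, graph, fixture.data)
            if m.provenance != "instance" and m.element:
                assert m.element in subtree_elements(model, label)


class TestEvaluateMatching:
    def test_all_correct(self):
        gold = ["a", "b", None]
        out = matching.evaluate_matching(gold, ["a", "b", None])
        assert out["precision"] == out["recall"] == out["rejection"] == 1.0

    def test_hand_computed_confusion(self):
        # 7 correct matches; 3 matches where no correct label existed;
        # 2 entities with a correct label wrongly rejected; 21 of the 24
        # truly dissimilar entities correctly rejected.  Hand-derived:
        # precision = 7/10, recall = 7/9, rejection = 21/24.
        gold = ["g"] * 7 + [None] * 3 + ["g"] * 2 + [None] * 21
        pred = ["g"] * 7 + ["x"] * 3 + [None] * 2 + [None] * 21
        out = matching.evaluate_matching(gold, pred)
        assert out["precision"] == pytest.approx(7 / 10)
        assert out["recall"] == pytest.approx(7 / 9)
        assert out["rejection"] == pytest.approx(21 / 24)

    def test_zero_denominators_flagged(self):
        out = matching.evaluate_matching(["a"], [None])
        assert out["precision"] == 0.0
        assert "precision" in out["zero_denominator"]

    def test_empty_gold_rejected(self):
        with pytest.raises(ValueError):
            matching.evaluate_matching([], [])


@pytest.fixture(scope="module")
def gold_pairs(model):
    pairs = [
        ("spectra score", fx.iri("spectral count")),
        ("spectral count", fx.iri("spectral count")),
        ("log2 ratios", fx.iri("log2 ratio")),
        ("genes", fx.iri("gene")),
        ("peptide counts", fx.iri("peptide count")),
        ("pathways", fx.iri("pathway")),
        ("researchers", fx.iri("researcher")),
        ("mass spectrometer", fx.iri("mass spectrometer")),
        ("plasmid", fx.iri("plasmid")),
        ("hypothesis statement", fx.iri("hypothesis statement")),
    ]
    # true dissimilars: vocabulary far from every element name
    pairs += [(w, None) for w in
              ("qwxz", "flurble", "zzzyx", "mnop vwxy", "jkqv", "xxqq zz")]
    return pairs


class TestSweep:
    def test_recall_and_rejection_trade_off(self, model, gold_pairs):
        rows = matching.sweep(gold_pairs, model)
        assert len(rows) == 5 * 5
        for measure in matching.MEASURES:
            series = [r for r in rows if r["measure"] == measure]
            series.sort(key=lambda r: r["threshold"])
            recalls = [r["recall"] for r in series]
            rejections = [r["rejection"] for r in series]
            assert all(a >= b - 1e-12 for a, b in zip(recalls, recalls[1:]))
            assert all(a <= b + 1e-12 for a, b in zip(rejections, rejections[1:]))

    def test_tsv_rendering(self, model, gold_pairs):
        rows = matching.sweep(gold_pairs, model, measures=("isub",), thresholds=(0.6,))
        tsv = matching.sweep_to_tsv(rows)
        assert tsv.splitlines()[0].startswith("measure\tthreshold")
        assert "isub" in tsv

    def test_combined_matching_recall_not_below_schema_only(self, model, graph, fixture):
        gold = [("genes", "material", fx.iri("gene")),
                ("spectra score", "data collection", fx.iri("spectral count")),
                ("protein phosphate", "parameter", fx.iri("gene function")),
                ("kinase activity", "parameter", fx.iri("gene function"))]

        def run(data):
            preds = []
            for text, label, _ in gold:
                m = matching.match_entity(ent(text, label), model, graph, data)
                preds.append(m.element)
            return matching.evaluate_matching([g for _, _, g in gold], preds)

        schema_only = run(None)
        combined = run(fixture.data)
        assert combined["recall"] >= schema_only["recall"]
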