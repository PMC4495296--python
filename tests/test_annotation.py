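"""Feature joins, the damaging-call rule, and evaluation metrics."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import matthews_corrcoef

from varcontact.alignment import align_chain
from varcontact.annotation import (
    AnnotationLoadError,
    AnnotationReportRow,
    AnnotationStore,
    FeatureRecord,
    PredictionRecord,
    RuleConfig,
    SomaticRecord,
    StructureContext,
    annotate_variant,
    classify_variant,
    compute_metrics,
    evaluate,
    features_at,
    load_annotation_tables,
)
from varcontact.fixtures import FixtureSpec, chain_sequences, generate_structure
from varcontact.structure3d import ResidueId, parse_pdb
from varcontact.variant_mapping import (
    IsoformCatalog,
    IsoformEntry,
    ProteinSubstitution,
)


class TestLoadTables:
    def test_feature_range_retrievable(self):
        store = load_annotation_tables(
            io.StringIO("P1\t10\t20\tdomain\tPfam:BRCT\n"))
        for pos in (10, 15, 20):
            assert len(features_at(store, "P1", pos)) == 1
        assert features_at(store, "P1", 21) == []
        assert features_at(store, "P1", 9) == []

    def test_somatic_hotspot_retrievable(self):
        store = load_annotation_tables(
            None,
            io.StringIO("P1\t427\tS\tF\tsample1\tbladder\tcarcinoma\n"))
        hits = store.somatic_at("P1", 427)
        assert len(hits) == 1
        assert hits[0].tumor_site == "bladder"

    def test_empty_prediction_table_is_valid(self):
        store = load_annotation_tables(None, None, io.StringIO(""))
        assert store.predictions == []

    def test_unknown_category_names_line(self):
        with pytest.raises(AnnotationLoadError, match="line 2"):
            load_annotation_tables(io.StringIO(
                "P1\t1\t2\tdomain\tok\nP1\t3\t4\tbogus_cat\tbad\n"))

    def test_unknown_method_rejected(self):
        with pytest.raises(AnnotationLoadError, match="line 1"):
            load_annotation_tables(
                None, None,
                io.StringIO("P1\t5\tA\tNotAMethod\t0.5\tdamaging\n"))

    def test_site_record_hit_at_exact_position(self):
        store = load_annotation_tables(
            io.StringIO("P1\t427\t427\tptm_site\tphospho\n"))
        assert len(features_at(store, "P1", 427)) == 1
        assert features_at(store, "P1", 428) == []


def _row(**kw):
    defaults = dict(substitution=ProteinSubstitution("P1", 10, "A", "V"))
    defaults.update(kw)
    return AnnotationReportRow(**defaults)


class TestClassifyVariant:
    def test_direct_catalytic_site_fires_d1(self):
        row = _row(direct_features=[
            FeatureRecord("P1", 10, 10, "catalytic_site", "active")])
        call, evidence = classify_variant(row)
        assert call == "damaging"
        assert evidence == ["d1:catalytic_site@10"]

    def test_domain_alone_does_not_fire(self):
        row = _row(direct_features=[FeatureRecord("P1", 1, 50, "domain", "D")])
        call, evidence = classify_variant(row)
        assert call == "no_evidence"
        assert evidence == []

    def test_all_tolerated_predictions_give_neutral(self):
        preds = [PredictionRecord("P1", 10, "V", m, 0.5, "tolerated")
                 for m in ("SIFT", "Polyphen2", "LRT")]
        call, evidence = classify_variant(_row(predictions=preds))
        assert call == "neutral"
        assert evidence == []

    def test_interface_only_fires_d3(self):
        row = _row(interface_flag=True, mapped_residue=ResidueId("A", 10, ""))
        call, evidence = classify_variant(row)
        assert call == "damaging"
        assert evidence == ["d3:interface@A/10"]

    def test_somatic_fires_d4(self):
        row = _row(somatic_matches=[
            SomaticRecord("P1", 10, "A", "V", "s1", "bladder", "carcinoma")])
        call, evidence = classify_variant(row)
        assert call == "damaging"
        assert evidence and evidence[0].startswith("d4:somatic@10")

    def test_prediction_majority_strict(self):
        def preds(calls):
            methods = ["SIFT", "Polyphen2", "LRT", "MutationTaster"]
            return [PredictionRecord("P1", 10, "V", m, 0.5, c)
                    for m, c in zip(methods, calls)]
        # 2/4 damaging: tie, does not fire
        call, _ = classify_variant(_row(predictions=preds(
            ["damaging", "damaging", "tolerated", "tolerated"])))
        assert call == "neutral"
        # 3/4 damaging: fires
        call, evidence = classify_variant(_row(predictions=preds(
            ["damaging", "damaging", "damaging", "tolerated"])))
        assert call == "damaging"
        assert evidence == ["d5:predictions(3/4 damaging)"]
        # unknowns do not vote: 2 damaging vs 1 tolerated + 1 unknown fires
        call, evidence = classify_variant(_row(predictions=preds(
            ["damaging", "damaging", "tolerated", "unknown"])))
        assert call == "damaging"
        assert evidence == ["d5:predictions(2/3 damaging)"]

    def test_sequence_adjacent_neighbor_excluded_from_d2(self):
        from varcontact.annotation import NeighborFeature
        site = FeatureRecord("P1", 11, 11, "ptm_site", "phospho")
        adjacent = NeighborFeature(site, ResidueId("A", 11, ""), 3.8,
                                   "intra_chain", sequence_adjacent=True)
        call, _ = classify_variant(_row(neighbor_features=[adjacent]))
        assert call == "no_evidence"
        spatial = NeighborFeature(site, ResidueId("A", 30, ""), 4.2,
                                  "intra_chain", sequence_adjacent=False)
        call, evidence = classify_variant(_row(neighbor_features=[spatial]))
        assert call == "damaging"
        assert evidence == ["d2:ptm_site@A/30(4.20A,intra_chain)"]

    def test_all_clauses_disabled_never_damaging(self):
        row = _row(
            direct_features=[FeatureRecord("P1", 10, 10, "catalytic_site", "")],
            interface_flag=True,
            somatic_matches=[SomaticRecord("P1", 10, "A", "V", "s", "", "")],
            predictions=[PredictionRecord("P1", 10, "V", "SIFT", 0.0,
                                          "damaging")],
        )
        call, evidence = classify_variant(row, RuleConfig.none())
        assert call == "neutral"  # predictions exist
        assert evidence == []

    def test_evidence_nonempty_iff_damaging(self):
        rows = [
            _row(),
            _row(direct_features=[FeatureRecord("P1", 10, 10, "ptm_site", "")]),
            _row(interface_flag=True, mapped_residue=ResidueId("A", 1, "")),
            _row(predictions=[PredictionRecord("P1", 10, "V", "CADD", 30.0,
                                               "damaging")]),
        ]
        for row in rows:
            call, evidence = classify_variant(row)
            assert (call == "damaging") == bool(evidence)


@pytest.fixture(scope="module")
def two_chain_context():
    """Engineered complex: P1 residue 30 contacts P2 residue 10 at 4.5 A,
    and P2 position 10 carries a binding site."""
    spec = FixtureSpec(seed=1, n_residues_per_chain=(60, 40),
                       contact_pairs=[(30, 10, 4.5)])
    seq_a, seq_b = chain_sequences(spec)
    structure = parse_pdb(generate_structure(spec), spec.structure_id,
                          "experimental", {"A": "P1", "B": "P2"})
    maps = {}
    for chain_id, pid, seq in (("A", "P1", seq_a), ("B", "P2", seq_b)):
        cseq, rids = structure.chain_sequence(chain_id)
        maps[chain_id] = align_chain(seq, cseq, rids, protein_id=pid,
                                     structure_id="S1", chain_id=chain_id)
    catalog = IsoformCatalog([IsoformEntry("G1", "P1", seq_a, True),
                              IsoformEntry("G2", "P2", seq_b, True)])
    store = AnnotationStore(
        features=[FeatureRecord("P2", 10, 10, "binding_site", "ligand"),
                  FeatureRecord("P1", 45, 45, "catalytic_site", "active")])
    return StructureContext(structure, maps), catalog, store, seq_a


class TestAnnotateVariant:
    def test_interface_contact_with_partner_site(self, two_chain_context):
        ctx, catalog, store, seq_a = two_chain_context
        sub = ProteinSubstitution("P1", 30, seq_a[29],
                                  "A" if seq_a[29] != "A" else "V")
        rows = annotate_variant(sub, store, [ctx], 5.0, catalog)
        assert len(rows) == 1
        row = rows[0]
        assert row.structure_id == "S1"
        assert row.interface_flag
        partner = [nf for nf in row.neighbor_features
                   if nf.relation == "interface_partner"]
        assert len(partner) == 1
        nf = partner[0]
        assert nf.feature.category == "binding_site"
        assert nf.residue_id == ResidueId("B", 10, "")
        assert nf.distance == pytest.approx(4.5, abs=0.01)
        assert row.call == "damaging"
        assert any(e.startswith("d2:binding_site@B/10") for e in row.evidence)
        assert any(e.startswith("d3:interface@") for e in row.evidence)

    def test_direct_catalytic_site(self, two_chain_context):
        ctx, catalog, store, seq_a = two_chain_context
        sub = ProteinSubstitution("P1", 45, seq_a[44],
                                  "A" if seq_a[44] != "A" else "V")
        rows = annotate_variant(sub, store, [ctx], 5.0, catalog)
        assert len(rows) == 1
        assert [f.category for f in rows[0].direct_features] == ["catalytic_site"]
        assert rows[0].call == "damaging"
        assert rows[0].evidence == ["d1:catalytic_site@45"]

    def test_no_structure_gives_single_structure_free_row(self,
                                                          two_chain_context):
        _ctx, catalog, store, _ = two_chain_context
        sub = ProteinSubstitution("P9", 5, "A", "V")
        rows = annotate_variant(sub, store, [], 5.0, None)
        assert len(rows) == 1
        assert rows[0].structure_id is None
        assert rows[0].mapped_residue is None

    def test_ref_mismatch_blocks_structural_annotation(self,
                                                       two_chain_context):
        ctx, catalog, store, seq_a = two_chain_context
        wrong_ref = "W" if seq_a[29] != "W" else "Y"
        sub = ProteinSubstitution("P1", 30, wrong_ref, "A")
        rows = annotate_variant(sub, store, [ctx], 5.0, catalog)
        assert len(rows) == 1
        assert "ref_mismatch" in rows[0].flags
        assert rows[0].structure_id is None

    def test_experimental_before_model_ordering(self, two_chain_context):
        ctx, catalog, store, seq_a = two_chain_context
        # clone the context as a homology model with a different id
        model_structure = parse_pdb(
            generate_structure(FixtureSpec(seed=1,
                                           n_residues_per_chain=(60, 40),
                                           contact_pairs=[(30, 10, 4.5)])),
            "M0", "model", {"A": "P1", "B": "P2"})
        model_ctx = StructureContext(model_structure, ctx.maps)
        sub = ProteinSubstitution("P1", 30, seq_a[29],
                                  "A" if seq_a[29] != "A" else "V")
        rows = annotate_variant(sub, store, [model_ctx, ctx], 5.0, catalog)
        assert [r.source for r in rows] == ["experimental", "model"]

    def test_neighbor_evidence_monotone_in_cutoff(self, two_chain_context):
        ctx, catalog, store, seq_a = two_chain_context
        sub = ProteinSubstitution("P1", 30, seq_a[29],
                                  "A" if seq_a[29] != "A" else "V")
        small = annotate_variant(sub, store, [ctx], 4.6, catalog)[0]
        large = annotate_variant(sub, store, [ctx], 6.0, catalog)[0]
        small_d23 = {e for e in small.evidence if e[:2] in ("d2", "d3")}
        large_d23 = {e for e in large.evidence if e[:2] in ("d2", "d3")}
        assert small_d23 <= large_d23

    def test_tiny_cutoff_removes_neighbor_features(self, two_chain_context):
        ctx, catalog, store, seq_a = two_chain_context
        sub = ProteinSubstitution("P1", 30, seq_a[29],
                                  "A" if seq_a[29] != "A" else "V")
        row = annotate_variant(sub, store, [ctx], 0.1, catalog)[0]
        assert row.neighbor_features == []
        assert not row.interface_flag


class TestComputeMetrics:
    def test_structure_aware_validation_counts(self):
        m = compute_metrics(tp=11, fp=0, fn=3, tn=10)
        assert m.rounded() == {"accuracy": 0.88, "recall": 0.79,
                               "precision": 1.00, "mcc": 0.78}

    def test_predictor_consensus_validation_counts(self):
        m = compute_metrics(tp=14, fp=4, fn=0, tn=6)
        assert m.rounded() == {"accuracy": 0.83, "recall": 1.00,
                               "precision": 0.78, "mcc": 0.68}

    def test_perfect_classifier(self):
        m = compute_metrics(5, 0, 0, 5)
        assert m.accuracy == 1.0
        assert m.mcc == 1.0

    def test_zero_denominators_give_nan(self):
        m = compute_metrics(0, 0, 3, 7)  # no positive calls
        assert math.isnan(m.precision)
        assert math.isnan(m.mcc)
        assert not math.isnan(m.accuracy)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(-1, 0, 0, 1)

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50), st.integers(0, 50))
    def test_mcc_bounded_and_matches_sklearn(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        m = compute_metrics(tp, fp, fn, tn)
        if not math.isnan(m.mcc):
            assert -1.0 <= m.mcc <= 1.0
            y_true = [1] * tp + [0] * fp + [1] * fn + [0] * tn
            y_pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
            assert m.mcc == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-9)
        assert m.accuracy == pytest.approx((tp + tn) / (tp + fp + fn + tn))


class TestEvaluate:
    @staticmethod
    def _variants(n):
        return [ProteinSubstitution("P1", i + 1, "A", "V") for i in range(n)]

    def test_all_correct_gives_mcc_one(self):
        vs = self._variants(6)
        labelled = [(v, "pathogenic") for v in vs[:3]] + \
                   [(v, "neutral") for v in vs[3:]]
        calls = {v: "damaging" for v in vs[:3]}
        calls.update({v: "neutral" for v in vs[3:]})
        assert evaluate(labelled, calls).mcc == 1.0

    def test_all_inverted_gives_mcc_minus_one(self):
        vs = self._variants(6)
        labelled = [(v, "pathogenic") for v in vs[:3]] + \
                   [(v, "neutral") for v in vs[3:]]
        calls = {v: "neutral" for v in vs[:3]}
        calls.update({v: "damaging" for v in vs[3:]})
        assert evaluate(labelled, calls).mcc == -1.0

    def test_no_evidence_counts_negative(self):
        vs = self._variants(2)
        labelled = [(vs[0], "pathogenic"), (vs[1], "neutral")]
        calls = {vs[0]: "no_evidence", vs[1]: "no_evidence"}
        m = evaluate(labelled, calls)
        assert (m.tp, m.fp, m.fn, m.tn) == (0, 0, 1, 1)
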