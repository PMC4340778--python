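"""Restorability and the five-step export loop."""

import datetime as dt

import pytest

from eavcare import (
    CompletenessSpec,
    ConflictError,
    ExportIncompleteError,
    Selection,
    SelectionCriteria,
    SourceDocMeta,
    TransformRule,
    apply_rules,
    canonical_equal,
    check_completeness,
    export_document,
    import_document,
    preselect,
    reconstruct_document,
)
from eavcare.exporter import canonical_form
from eavcare.fixtures import GenParams, import_corpus

META = SourceDocMeta(author="Nurse A", received_at=dt.datetime(2013, 2, 4))


class TestReconstruction:
    @pytest.mark.parametrize("raw", [
        b'<a x="1"/>',
        b"<a>t1<b/>t2</a>",
        b'<a x="042"><b y="true">text &amp; more</b><b/></a>',
        b'<p:a xmlns:p="urn:x"><p:b p:z="1"/></p:a>',
        b'<a><b>  spaced  text  </b></a>',
    ])
    def test_round_trip_canonical_equality(self, store, raw):
        report = import_document(store, raw, META)
        rebuilt = reconstruct_document(store, report.source_doc_id)
        assert canonical_equal(rebuilt, raw)

    def test_mixed_content_text_order_preserved(self, store):
        raw = b"<a>t1<b/>t2<b/>t3</a>"
        report = import_document(store, raw, META)
        rebuilt = reconstruct_document(store, report.source_doc_id)
        assert canonical_form(rebuilt) == canonical_form(raw)

    def test_lexical_fidelity_042_not_42(self, store):
        report = import_document(store, b'<a x="042"/>', META)
        rebuilt = reconstruct_document(store, report.source_doc_id)
        assert b'x="042"' in rebuilt

    def test_generated_corpus_round_trips(self, store):
        _m, reports = import_corpus(store, GenParams(seed=30, n_docs=10))
        for rep in reports:
            rebuilt = reconstruct_document(store, rep.source_doc_id)
            assert canonical_equal(rebuilt, store.get_raw(rep.source_doc_id))

    def test_unknown_doc_raises(self, store):
        from eavcare import UnknownDocumentError

        with pytest.raises(UnknownDocumentError):
            reconstruct_document(store, 404)


class TestPreselect:
    @pytest.fixture
    def loaded(self, store):
        manifest, reports = import_corpus(store, GenParams(seed=31, n_docs=4))
        return manifest, reports

    def test_body_only_excludes_header_facts(self, store, loaded):
        sel = preselect(store, SelectionCriteria(is_metadata=False))
        assert sel.facts
        assert all(not f.is_metadata for f in sel.facts)

    def test_one_doc_criteria_stays_within_doc(self, store, loaded):
        _m, reports = loaded
        doc = reports[1].source_doc_id
        sel = preselect(store, SelectionCriteria(doc_ids=[doc]))
        assert {f.source_doc_id for f in sel.facts} == {doc}
        assert len(sel) == reports[1].n_values

    def test_path_pattern_selects_exactly_manifest_section(self, store, loaded):
        manifest, reports = loaded
        pattern = ("/ClinicalDocument[1]/component[*]/structuredBody[1]"
                   "/component[*]/NursingProcess[1]/**")
        sel = preselect(store, SelectionCriteria(path_patterns=[pattern]))
        want = set()
        for i, man in enumerate(manifest.docs):
            for idx in man.section_facts.get("NursingProcess", []):
                f = man.facts[idx]
                want.add((reports[i].source_doc_id, f.path, f.lexical))
        got = {(f.source_doc_id, f.entity_path, f.lexical) for f in sel.facts}
        assert got == want

    def test_time_window_filters_by_receipt(self, store, loaded):
        _m, reports = loaded
        cutoff = dt.datetime(2013, 2, 4, 12)  # docs are 6h apart from 08:00
        sel = preselect(store, SelectionCriteria(received_to=cutoff))
        assert {f.source_doc_id for f in sel.facts} == \
            {reports[0].source_doc_id}

    def test_nothing_matching_is_empty_not_error(self, store, loaded):
        sel = preselect(store, SelectionCriteria(path_patterns=["/nope[1]"]))
        assert len(sel) == 0


class TestApplyRules:
    def test_empty_selection_yields_empty_tree(self, store):
        tree = apply_rules(Selection(()), [], store)
        assert tree.root is None

    def test_identity_rule_places_value(self, store):
        import_document(store, b'<a x="1"/>', META)
        sel = preselect(store, SelectionCriteria())
        rule = TransformRule("r1", "/a[1]/@x", "/out/item/@x")
        tree = apply_rules(sel, [rule], store)
        assert tree.serialize().endswith(b'<out><item x="1"/></out>')

    def test_value_transform_applies(self, store):
        import_document(store, b'<a d="2013-02-04"/>', META)
        sel = preselect(store, SelectionCriteria())
        rule = TransformRule("r1", "/a[1]/@d", "/out/when/#text",
                             value_transform="date_iso_to_german")
        tree = apply_rules(sel, [rule], store)
        assert b"<when>04.02.2013</when>" in tree.serialize()

    def test_conflicting_rules_raise_naming_both(self, store):
        import_document(store, b'<a x="1" y="2"/>', META)
        sel = preselect(store, SelectionCriteria())
        rules = [
            TransformRule("rx", "/a[1]/@x", "/out/item/@v"),
            TransformRule("ry", "/a[1]/@y", "/out/item/@v"),
        ]
        with pytest.raises(ConflictError, match="rx.*ry|ry.*rx"):
            apply_rules(sel, rules, store)

    def test_agreeing_rules_do_not_conflict(self, store):
        import_document(store, b'<a x="1"><b x="1"/></a>', META)
        sel = preselect(store, SelectionCriteria())
        rules = [TransformRule("r", "/**/@x", "/out/item/@v")]
        tree = apply_rules(sel, rules, store)
        assert b'<item v="1"/>' in tree.serialize()

    def test_unmatched_facts_logged_not_fatal(self, store):
        import_document(store, b'<a x="1" y="2"/>', META)
        sel = preselect(store, SelectionCriteria())
        tree = apply_rules(sel, [TransformRule("r", "/a[1]/@x",
                                               "/out/item/@x")], store)
        assert any("y" in n for n in tree.notices)


class TestCompleteness:
    def _tree(self, store, raw, rules):
        import_document(store, raw, META)
        return apply_rules(preselect(store, SelectionCriteria()), rules, store)

    def test_all_required_populated_returns_empty(self, store):
        tree = self._tree(store, b'<a x="1"/>',
                          [TransformRule("r", "/a[1]/@x", "/out/item/@x")])
        assert check_completeness(
            tree, CompletenessSpec(("/out/item/@x",), root_name="out")
        ) == []

    def test_exactly_the_absent_paths_returned(self, store):
        tree = self._tree(store, b'<a x="1"/>',
                          [TransformRule("r", "/a[1]/@x", "/out/item/@x")])
        spec = CompletenessSpec((
            "/out/item/@x", "/out/item/@y", "/out/other/#text",
        ))
        assert check_completeness(tree, spec) == [
            "/out/item/@y", "/out/other/#text",
        ]

    def test_empty_spec_is_always_complete(self, store):
        tree = self._tree(store, b'<a x="1"/>',
                          [TransformRule("r", "/a[1]/@x", "/out/item/@x")])
        assert check_completeness(tree, CompletenessSpec(())) == []

    def test_wrong_root_reported_as_validity_failure(self, store):
        tree = self._tree(store, b'<a x="1"/>',
                          [TransformRule("r", "/a[1]/@x", "/out/item/@x")])
        missing = check_completeness(
            tree, CompletenessSpec((), root_name="summary")
        )
        assert missing == ["root:summary"]


class TestExportLoop:
    @pytest.fixture
    def setting(self, store):
        """Ten source attributes mapping 1:1 onto ten required slots."""
        attrs = " ".join(f'a{i:02d}="{i}"' for i in range(10))
        raw = f"<doc {attrs}/>".encode()
        import_document(store, raw, META)
        rules = [
            TransformRule(f"r{i:02d}", f"/doc[1]/@a{i:02d}",
                          f"/out/f{i:02d}/@v")
            for i in range(10)
        ]
        spec = CompletenessSpec(
            tuple(f"/out/f{i:02d}/@v" for i in range(10)), root_name="out"
        )
        return rules, spec

    def test_complete_first_pass_is_one_iteration(self, store, setting):
        rules, spec = setting
        out, iterations = export_document(
            store, SelectionCriteria(), rules, spec, lambda s, m: s
        )
        assert iterations == 1
        assert out.startswith(b"<?xml")

    def test_scripted_selector_m_short_takes_m_plus_1_iterations(
            self, store, setting):
        rules, spec = setting
        dropped = []

        def selector(selection, missing):
            if not missing and not dropped:  # initial manual select: 4 short
                dropped.extend(selection.facts[-4:])
                return selection.without(4)
            if missing and dropped:
                return selection.plus([dropped.pop()])
            return selection

        out, iterations = export_document(
            store, SelectionCriteria(), rules, spec, selector
        )
        assert iterations == 5

    def test_selector_that_never_fixes_hits_the_bound(self, store, setting):
        rules, spec = setting
        with pytest.raises(ExportIncompleteError) as err:
            export_document(
                store, SelectionCriteria(), rules, spec,
                lambda s, m: s.without(4) if not m else s,
                max_iterations=3,
            )
        assert len(err.value.missing) == 4
        assert err.value.iterations == 3

    def test_export_is_deterministic(self, store, setting):
        rules, spec = setting
        out1, _ = export_document(store, SelectionCriteria(), rules, spec,
                                  lambda s, m: s)
        out2, _ = export_document(store, SelectionCriteria(), rules, spec,
                                  lambda s, m: s)
        assert out1 == out2

    def test_missing_set_shrinks_monotonically(self, store, setting):
        """When the selector only adds facts back, missing never grows."""
        rules, spec = setting
        seen = []
        dropped = []

        def selector(selection, missing):
            seen.append(set(missing))
            if not missing and not dropped:
                dropped.extend(selection.facts[-3:])
                return selection.without(3)
            if missing and dropped:
                return selection.plus([dropped.pop()])
            return selection

        export_document(store, SelectionCriteria(), rules, spec, selector)
        checks = seen[1:]  # the post-check calls carry the missing sets
        for earlier, later in zip(checks, checks[1:]):
            assert later <= earlier


def test_rule_and_spec_yaml_round_trip(tmp_path, store):
    import datetime as dt

    from eavcare.exporter import load_completeness_spec, load_rules

    cfg = tmp_path / "rules.yml"
    cfg.write_text(
        "rules:\n"
        "  - {name: r1, source: '/a[1]/@x', target: '/out/item/@x'}\n"
        "completeness:\n"
        "  root: out\n"
        "  required: ['/out/item/@x']\n"
    )
    rules = load_rules(str(cfg))
    spec = load_completeness_spec(str(cfg))
    import_document(store, b'<a x="1"/>', META)
    out, iterations = export_document(
        store, SelectionCriteria(), rules, spec, lambda s, m: s
    )
    assert iterations == 1 and b'x="1"' in out
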