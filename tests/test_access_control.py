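"""View fragments, grants and query-time enforcement."""

import datetime as dt
import random

import pytest

from eavcare import (
    AuthorizationError,
    ConflictError,
    ValidationError,
    ValueFact,
    all_tuples,
    define_view,
    grant,
    query_as,
    revoke,
)
from eavcare.access_control import (
    ViewSpec,
    evaluate_view,
    load_access_config,
    readable_fragment,
    update_fact_as,
    delete_fact_as,
)
from eavcare.fixtures import GenParams, import_corpus
from eavcare.query_engine import QuerySpec, fact_records

MEDS_PATTERN = ("/ClinicalDocument[1]/component[*]/structuredBody[1]"
                "/component[*]/MedicalInformation[1]/**")


@pytest.fixture
def loaded(store):
    manifest, reports = import_corpus(
        store, GenParams(seed=40, n_docs=8,
                         planted_terms=(("hemoglobin", 3),))
    )
    return manifest, reports


class TestViews:
    def test_duplicate_view_name_conflicts(self, store):
        define_view(store, ViewSpec(name="v"))
        with pytest.raises(ConflictError):
            define_view(store, ViewSpec(name="v"))

    def test_unrestricted_view_evaluates_to_all_tuples(self, store, loaded):
        vid = define_view(store, ViewSpec(name="all"))
        from eavcare.access_control import get_view

        frag = evaluate_view(store, get_view(store, vid))
        assert [f.as_tuple() for f in frag] == all_tuples(store)

    def test_time_window_view_excludes_older_documents(self, store, loaded):
        _m, reports = loaded
        # docs arrive 6h apart from 2013-02-04 08:00; previous-day window
        spec = ViewSpec(name="previous-day",
                        received_from=dt.datetime(2013, 2, 4),
                        received_to=dt.datetime(2013, 2, 5))
        frag = evaluate_view(store, spec)
        day_one = {r.source_doc_id for r in frag}
        assert day_one == {reports[i].source_doc_id for i in range(3)}

    def test_vertical_medication_view_matches_manifest(self, store, loaded):
        manifest, reports = loaded
        frag = evaluate_view(
            store, ViewSpec(name="meds", path_patterns=(MEDS_PATTERN,))
        )
        got = {(f.source_doc_id, f.entity_path, f.lexical) for f in frag}
        want = set()
        for i, man in enumerate(manifest.docs):
            for idx in man.section_facts.get("MedicalInformation", []):
                f = man.facts[idx]
                want.add((reports[i].source_doc_id, f.path, f.lexical))
        assert got == want


class TestGrants:
    def test_empty_rights_rejected(self, store):
        vid = define_view(store, ViewSpec(name="v"))
        with pytest.raises(ValidationError):
            grant(store, "nurse", vid, [])

    def test_union_of_two_views(self, store, loaded):
        vid_hdr = define_view(store, ViewSpec(name="hdr", is_metadata=True))
        vid_meds = define_view(
            store, ViewSpec(name="meds", path_patterns=(MEDS_PATTERN,))
        )
        grant(store, "nurse", vid_hdr, ["read"])
        grant(store, "nurse", vid_meds, ["read"])
        visible = {f.value_id for f in readable_fragment(store, "nurse")}
        hdr = {f.value_id for f in evaluate_view(
            store, ViewSpec(name="h2", is_metadata=True))}
        meds = {f.value_id for f in evaluate_view(
            store, ViewSpec(name="m2", path_patterns=(MEDS_PATTERN,)))}
        assert visible == hdr | meds

    def test_read_only_role_cannot_delete(self, store, loaded):
        vid = define_view(store, ViewSpec(name="all"))
        grant(store, "clerk", vid, ["read"])
        target = fact_records(store)[0].value_id
        with pytest.raises(AuthorizationError):
            delete_fact_as(store, "clerk", target)

    def test_revoking_sole_grant_removes_access(self, store, loaded):
        vid = define_view(store, ViewSpec(name="all"))
        gid = grant(store, "clerk", vid, ["read"])
        assert query_as(store, "clerk", QuerySpec("all"))
        revoke(store, gid)
        with pytest.raises(AuthorizationError):
            query_as(store, "clerk", QuerySpec("all"))


class TestQueryAs:
    def test_all_access_role_sees_unrestricted_result(self, store, loaded):
        vid = define_view(store, ViewSpec(name="all"))
        grant(store, "admin", vid, ["read"])
        assert query_as(store, "admin", QuerySpec("all")) == all_tuples(store)

    def test_header_only_role_sees_only_metadata_facts(self, store, loaded):
        vid = define_view(store, ViewSpec(name="hdr", is_metadata=True))
        grant(store, "clerk", vid, ["read"])
        rows = query_as(store, "clerk", QuerySpec("all"))
        header_ids = {f.value_id for f in fact_records(store)
                      if f.is_metadata}
        assert rows
        assert len(rows) == len(header_ids)

    def test_no_read_grant_is_authorization_error(self, store, loaded):
        with pytest.raises(AuthorizationError):
            query_as(store, "stranger", QuerySpec("all"))

    def test_term_query_as_restricted_role_equals_oracle_filter(
            self, store, loaded):
        vid = define_view(
            store, ViewSpec(name="meds", path_patterns=(MEDS_PATTERN,))
        )
        grant(store, "pharmacist", vid, ["read"])
        got = query_as(store, "pharmacist", QuerySpec("term", "hemoglobin"))
        # oracle: brute-force filter of the unrestricted result
        from eavcare.query_engine import find_documents
        from eavcare._patterns import match_fact, parse_pattern

        pat = parse_pattern(MEDS_PATTERN)
        docs = set(find_documents(store, "hemoglobin"))
        want = [r.as_tuple() for r in fact_records(store)
                if r.source_doc_id in docs
                and match_fact(pat, r.entity_path, r.attribute)]
        assert got == want

    def test_containment_under_any_grants(self, store, loaded):
        vid = define_view(store, ViewSpec(name="hdr", is_metadata=True))
        grant(store, "clerk", vid, ["read"])
        full = all_tuples(store)
        restricted = query_as(store, "clerk", QuerySpec("all"))
        # multiset containment
        from collections import Counter

        assert not Counter(restricted) - Counter(full)

    def test_adding_grants_never_shrinks_visible_set(self, store, loaded):
        """Monotonicity over a sequence of random grant additions."""
        rng = random.Random(99)
        specs = [
            ViewSpec(name="hdr", is_metadata=True),
            ViewSpec(name="body", is_metadata=False),
            ViewSpec(name="meds", path_patterns=(MEDS_PATTERN,)),
            ViewSpec(name="codes", attributes=frozenset({"code", "value"})),
            ViewSpec(name="early", received_to=dt.datetime(2013, 2, 5)),
        ]
        vids = [define_view(store, s) for s in specs]
        grant(store, "r", rng.choice(vids), ["read"])
        prev = {f.value_id for f in readable_fragment(store, "r")}
        for _ in range(20):
            grant(store, "r", rng.choice(vids), ["read"])
            cur = {f.value_id for f in readable_fragment(store, "r")}
            assert prev <= cur
            prev = cur


class TestWriteRights:
    def test_update_supersedes_rather_than_overwrites(self, store, loaded):
        vid = define_view(store, ViewSpec(name="all"))
        grant(store, "admin", vid, ["read", "update"])
        target = fact_records(store)[0]
        n_before = store.n_values()
        new_id = update_fact_as(store, "admin", target.value_id, "edited")
        assert store.get_value(new_id).lexical == "edited"
        assert store.n_values() == n_before  # one superseded, one added
        live_ids = {f.value_id for f in fact_records(store)}
        assert target.value_id not in live_ids
        assert new_id in live_ids

    def test_update_outside_fragment_denied(self, store, loaded):
        vid = define_view(store, ViewSpec(name="hdr", is_metadata=True))
        grant(store, "clerk", vid, ["read", "update"])
        body_fact = next(f for f in fact_records(store) if not f.is_metadata)
        with pytest.raises(AuthorizationError):
            update_fact_as(store, "clerk", body_fact.value_id, "x")


def test_access_config_yaml(tmp_path, store, loaded):
    cfg = tmp_path / "access.yml"
    cfg.write_text(
        "views:\n"
        "  - name: header-only\n"
        "    horizontal: {is_metadata: true}\n"
        "grants:\n"
        "  - {role: clerk, view: header-only, rights: [read]}\n"
    )
    ids = load_access_config(store, str(cfg))
    assert "header-only" in ids
    rows = query_as(store, "clerk", QuerySpec("all"))
    assert rows and len(rows) < len(all_tuples(store))
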