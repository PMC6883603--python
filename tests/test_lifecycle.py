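"""Moderation workflow: transition guards, event sourcing, replay."""

import random
from datetime import date

import pytest

from varkb.lifecycle import (
    Actor,
    AuthorizationError,
    CommentRequiredError,
    CurationEngine,
    Event,
    GateError,
    LifecycleError,
    SelfAcceptanceError,
    UnknownEntityError,
)
from varkb.models import Assertion, EvidenceItem, ModerationRecord, SourceRef

from conftest import make_evidence_item

TODAY = date(2019, 11, 29)
VALID_COI = date(2019, 6, 1)
EXPIRED_COI = date(2017, 1, 1)


@pytest.fixture
def engine():
    return CurationEngine(
        actors={
            "editor1": Actor("editor1", "Editor", VALID_COI),
            "editor2": Actor("editor2", "Editor", VALID_COI),
            "stale_editor": Actor("stale_editor", "Editor", EXPIRED_COI),
            "no_coi_editor": Actor("no_coi_editor", "Editor", None),
            "admin": Actor("admin", "Admin", VALID_COI),
        },
        today=TODAY,
    )


def fresh_item(eid="EID1", **overrides):
    return make_evidence_item(eid=eid, moderation=ModerationRecord(), **overrides)


class TestSubmission:
    def test_submit_auto_creates_gene_and_variant(self, engine):
        engine.submit_evidence(fresh_item(), "curator1")
        assert "EGFR" in engine.corpus.genes
        assert "EGFR:L858R" in engine.corpus.variants
        assert engine.corpus.evidence_items["EID1"].moderation.state == "submitted"

    def test_duplicate_pending_submission_warns(self, engine):
        engine.submit_evidence(fresh_item("EID1"), "curator1")
        _, warnings = engine.submit_evidence(fresh_item("EID2"), "curator2")
        assert warnings and "duplicate" in warnings[0]

    def test_unknown_actor_defaults_to_curator(self, engine):
        engine.submit_evidence(fresh_item(), "drive-by")
        with pytest.raises(AuthorizationError):
            engine.accept("evidence", "EID1", "drive-by")


class TestAcceptance:
    def test_editor_accepts_another_curators_item(self, engine):
        engine.submit_evidence(fresh_item(), "curator1")
        engine.accept("evidence", "EID1", "editor1")
        record = engine.corpus.evidence_items["EID1"].moderation
        assert record.state == "accepted" and record.decided_by == "editor1"

    def test_self_acceptance_forbidden_even_for_editors(self, engine):
        engine.submit_evidence(fresh_item(), "editor1")
        with pytest.raises(SelfAcceptanceError):
            engine.accept("evidence", "EID1", "editor1")

    def test_curator_cannot_accept(self, engine):
        engine.submit_evidence(fresh_item(), "curator1")
        with pytest.raises(AuthorizationError):
            engine.accept("evidence", "EID1", "curator2")

    @pytest.mark.parametrize("editor", ["stale_editor", "no_coi_editor"])
    def test_coi_requirement(self, engine, editor):
        engine.submit_evidence(fresh_item(), "curator1")
        with pytest.raises(AuthorizationError, match="conflict-of-interest"):
            engine.accept("evidence", "EID1", editor)

    def test_assertion_gate_requires_accepted_evidence(self, engine):
        engine.submit_evidence(fresh_item(), "curator1")
        assertion = Assertion(
            aid="AID1", gene_symbol="EGFR", variant_name="L858R",
            assertion_type="Predictive", supporting_eids=["EID1"],
        )
        engine.submit_assertion(assertion, "curator1")
        with pytest.raises(GateError):
            engine.accept("assertion", "AID1", "editor1")
        engine.accept("evidence", "EID1", "editor1")
        engine.accept("assertion", "AID1", "editor1")
        assert engine.corpus.assertions["AID1"].moderation.state == "accepted"


class TestRejection:
    def test_submitter_may_reject_own_item(self, engine):
        engine.submit_evidence(fresh_item(), "curator1")
        engine.reject("evidence", "EID1", "curator1", "wrong source cited")
        assert engine.corpus.evidence_items["EID1"].moderation.state == "rejected"

    def test_unrelated_curator_may_not_reject(self, engine):
        engine.submit_evidence(fresh_item(), "curator1")
        with pytest.raises(AuthorizationError):
            engine.reject("evidence", "EID1", "curator2", "nope")

    def test_rejection_requires_comment(self, engine):
        engine.submit_evidence(fresh_item(), "curator1")
        with pytest.raises(CommentRequiredError):
            engine.reject("evidence", "EID1", "editor1", "   ")

    def test_rejecting_last_accepted_item_demotes_assertion(self, engine):
        engine.submit_evidence(fresh_item(), "curator1")
        engine.accept("evidence", "EID1", "editor1")
        assertion = Assertion(
            aid="AID1", gene_symbol="EGFR", variant_name="L858R",
            assertion_type="Predictive", supporting_eids=["EID1"],
        )
        engine.submit_assertion(assertion, "curator1")
        engine.accept("assertion", "AID1", "editor1")
        engine.reject("evidence", "EID1", "editor2", "retracted publication")
        record = engine.corpus.assertions["AID1"].moderation
        assert record.state == "submitted" and record.flagged


class TestRevisions:
    def test_revision_queued_without_mutating_entity(self, engine):
        engine.submit_evidence(fresh_item(evidence_level="C"), "curator1")
        engine.propose_revision(
            "evidence", "EID1", "evidence_level", "B",
            "larger trial than initially read", "curator2",
        )
        assert engine.corpus.evidence_items["EID1"].evidence_level == "C"
        engine.accept_revision("evidence", "EID1", 0, "editor1")
        assert engine.corpus.evidence_items["EID1"].evidence_level == "B"

    def test_revision_requires_comment(self, engine):
        engine.submit_evidence(fresh_item(), "curator1")
        with pytest.raises(CommentRequiredError):
            engine.propose_revision("evidence", "EID1", "evidence_level", "B", "", "c2")

    def test_own_revision_not_acceptable(self, engine):
        engine.submit_evidence(fresh_item(), "curator1")
        engine.propose_revision(
            "evidence", "EID1", "evidence_level", "B", "reason", "editor1"
        )
        with pytest.raises(SelfAcceptanceError):
            engine.accept_revision("evidence", "EID1", 0, "editor1")

    def test_unrevisable_field_rejected(self, engine):
        engine.submit_evidence(fresh_item(), "curator1")
        with pytest.raises(LifecycleError, match="not revisable"):
            engine.propose_revision("evidence", "EID1", "eid", "EID9", "why", "c2")

    def test_accepted_rule_breaking_revision_surfaces_in_validation(
        self, engine, registries
    ):
        engine.submit_evidence(fresh_item(), "curator1")
        engine.propose_revision(
            "evidence", "EID1", "drugs", [], "remove drug", "curator2"
        )
        engine.accept_revision("evidence", "EID1", 0, "editor1")
        from varkb.rules import validate_evidence_item

        report = validate_evidence_item(
            engine.corpus.evidence_items["EID1"], registries
        )
        assert "EID_DRUGS_REQUIRED" in [v.rule_id for v in report]


class TestFlags:
    def test_flag_and_resolve(self, engine):
        engine.submit_evidence(fresh_item(), "curator1")
        engine.flag("evidence", "EID1", "curator2", "level looks inflated")
        engine.flag("evidence", "EID1", "curator3", "same concern")  # idempotent
        assert engine.corpus.evidence_items["EID1"].moderation.flagged
        engine.resolve_flag("evidence", "EID1", "editor1", "level verified against source")
        assert not engine.corpus.evidence_items["EID1"].moderation.flagged

    def test_flag_unknown_entity(self, engine):
        with pytest.raises(UnknownEntityError):
            engine.flag("evidence", "EID404", "curator1", "x")


class TestEventLog:
    def test_replay_reproduces_corpus_exactly(self, engine):
        engine.submit_evidence(fresh_item("EID1"), "curator1")
        engine.submit_evidence(fresh_item("EID2", variant_name="T790M"), "curator2")
        engine.accept("evidence", "EID1", "editor1")
        engine.propose_revision(
            "evidence", "EID2", "evidence_rating", 2, "small cohort", "curator1"
        )
        engine.accept_revision("evidence", "EID2", 0, "editor2")
        engine.flag("evidence", "EID2", "curator3", "check me")
        engine.reject("evidence", "EID2", "editor1", "insufficient detail")

        log_lines = engine.dump_events().splitlines()
        replayed = CurationEngine.replay([Event.from_json(l) for l in log_lines])
        assert replayed.corpus.to_dict() == engine.corpus.to_dict()
        # replaying the replayed log is a fixed point
        again = CurationEngine.replay(
            [Event.from_json(l) for l in replayed.dump_events().splitlines()]
        )
        assert again.corpus.to_dict() == replayed.corpus.to_dict()

    def test_accepted_only_reachable_through_submitted(self, engine):
        engine.submit_evidence(fresh_item(), "curator1")
        engine.reject("evidence", "EID1", "curator1", "withdrawn")
        states = [
            e for e in engine.events if e.entity_ref == "EID1" and e.action != "submit"
        ]
        assert [e.action for e in states] == ["reject"]


# ---------------------------------------------------------------------------
# randomized action streams: safety invariants hold under every sequence
# ---------------------------------------------------------------------------

ACTORS = {
    "c1": Actor("c1"),
    "c2": Actor("c2"),
    "ed1": Actor("ed1", "Editor", VALID_COI),
    "ed2": Actor("ed2", "Editor", VALID_COI),
    "stale": Actor("stale", "Editor", EXPIRED_COI),
}


def check_invariants(engine):
    for collection in (engine.corpus.evidence_items, engine.corpus.assertions):
        for entity in collection.values():
            record = entity.moderation
            if record.state == "accepted":
                assert record.decided_by != record.submitter_id, "self-acceptance"
    for assertion in engine.corpus.assertions.values():
        if assertion.moderation.state == "accepted":
            assert any(
                eid in engine.corpus.evidence_items
                and engine.corpus.evidence_items[eid].moderation.state == "accepted"
                for eid in assertion.supporting_eids
            ), "accepted assertion without accepted evidence"


def run_random_sequence(seed, n_actions=10):
    rng = random.Random(seed)
    engine = CurationEngine(actors=ACTORS, today=TODAY)
    next_id = [0]

    def random_action():
        roll = rng.random()
        actor = rng.choice(sorted(ACTORS))
        eids = sorted(engine.corpus.evidence_items)
        aids = sorted(engine.corpus.assertions)
        if roll < 0.3 or not eids:
            next_id[0] += 1
            engine.submit_evidence(
                fresh_item(f"EID{next_id[0]}", variant_name=rng.choice(["L858R", "T790M"])),
                actor,
            )
        elif roll < 0.45:
            next_id[0] += 1
            engine.submit_assertion(
                Assertion(
                    aid=f"AID{next_id[0]}",
                    gene_symbol="EGFR",
                    variant_name=rng.choice(["L858R", "T790M"]),
                    assertion_type="Predictive",
                    supporting_eids=rng.sample(eids, k=min(len(eids), rng.randint(1, 3))),
                ),
                actor,
            )
        elif roll < 0.65:
            kind, refs = rng.choice([("evidence", eids), ("assertion", aids)])
            if refs:
                engine.accept(kind, rng.choice(refs), actor)
        elif roll < 0.85:
            kind, refs = rng.choice([("evidence", eids), ("assertion", aids)])
            if refs:
                engine.reject(kind, rng.choice(refs), actor, "randomized rejection")
        else:
            if eids:
                engine.flag("evidence", rng.choice(eids), actor, "spot check")

    for _ in range(n_actions):
        try:
            random_action()
        except LifecycleError:
            pass
        check_invariants(engine)
    return engine


def test_random_action_streams_preserve_safety_invariants():
    for seed in range(200):
        run_random_sequence(seed)
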