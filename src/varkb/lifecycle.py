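"""Event-sourced curation/moderation workflow.

Every curatable entity (evidence item, assertion) cycles through
submitted -> accepted | rejected, with optional revisions and flags along the
way. Guards encode the SOP's moderation rules: only Editors/Admins with a
current conflict-of-interest statement may decide; nobody accepts their own
submission (though anyone may reject their own); rejections and revisions
require a comment; an assertion cannot be accepted until at least one of its
supporting evidence items is accepted, and losing the last accepted item
demotes an accepted assertion back to submitted with an auto-flag.

The append-only event log is the source of truth; current state is a fold
over events, so replaying a log deterministically reproduces the corpus.
Timestamps are logical sequence numbers — no wall-clock dependence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Optional

from .models import Assertion, EvidenceItem, GeneRecord, Revision, VariantRecord
from .corpus import Corpus

DEFAULT_COI_WINDOW_DAYS = 365


class LifecycleError(Exception):
    """Base class for moderation-rule violations raised by transitions."""


class AuthorizationError(LifecycleError):
    """Actor lacks the role, COI statement, or ownership the action requires."""


class SelfAcceptanceError(AuthorizationError):
    """Curators may reject, but never accept, their own submissions/revisions."""


class GateError(LifecycleError):
    """Assertion acceptance gate: at least one accepted supporting item needed."""


class CommentRequiredError(LifecycleError):
    """Rejections and proposed revisions require a rationale comment."""


class UnknownEntityError(LifecycleError, KeyError):
    """Entity reference does not resolve in the corpus."""


@dataclass(frozen=True)
class Actor:
    actor_id: str
    role: str = "Curator"
    coi_statement_date: Optional[date] = None


@dataclass(frozen=True)
class Event:
    """One appended workflow action; ``seq`` doubles as the logical timestamp."""

    seq: int
    action: str
    actor_id: str
    entity_kind: str
    entity_ref: str
    payload: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seq": self.seq,
                "action": self.action,
                "actor": self.actor_id,
                "entity_kind": self.entity_kind,
                "entity_ref": self.entity_ref,
                "payload": self.payload,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, line: str) -> "Event":
        data = json.loads(line)
        return cls(
            seq=data["seq"],
            action=data["action"],
            actor_id=data["actor"],
            entity_kind=data["entity_kind"],
            entity_ref=data["entity_ref"],
            payload=data.get("payload", {}),
        )


#: Fields a revision may target on each entity kind.
REVISABLE_FIELDS = {
    "evidence": {
        "evidence_statement", "evidence_level", "evidence_rating",
        "evidence_direction", "clinical_significance", "disease_doid",
        "drugs", "drug_interaction_type", "phenotypes", "variant_origin",
    },
    "assertion": {
        "summary", "description", "clinical_significance", "amp_tier",
        "amp_level", "acmg_classification", "nccn_guideline", "drugs",
        "drug_interaction_type",
    },
}


class CurationEngine:
    """Applies moderation actions to a corpus while appending an event log."""

    def __init__(
        self,
        corpus: Optional[Corpus] = None,
        actors: Optional[dict[str, Actor]] = None,
        today: Optional[date] = None,
        coi_window_days: int = DEFAULT_COI_WINDOW_DAYS,
    ):
        self.corpus = corpus if corpus is not None else Corpus()
        self.actors = dict(actors or {})
        self.today = today or date(2019, 11, 29)
        self.coi_window = timedelta(days=coi_window_days)
        self.events: list[Event] = []

    # -- helpers -----------------------------------------------------------

    def _actor(self, actor_id: str) -> Actor:
        # unknown actors participate as Curators by default
        return self.actors.get(actor_id, Actor(actor_id=actor_id))

    def _entity(self, kind: str, ref: str):
        collection = {
            "evidence": self.corpus.evidence_items,
            "assertion": self.corpus.assertions,
            "variant": self.corpus.variants,
            "gene": self.corpus.genes,
        }.get(kind)
        if collection is None or ref not in collection:
            raise UnknownEntityError(f"{kind} {ref!r} not in corpus")
        return collection[ref]

    def _record(self, action: str, actor_id: str, kind: str, ref: str, **payload):
        # the log is self-contained: each event carries the acting actor's
        # role/COI so a replay needs nothing but the log itself
        actor = self._actor(actor_id)
        payload.setdefault("actor_role", actor.role)
        payload.setdefault(
            "actor_coi",
            actor.coi_statement_date.isoformat() if actor.coi_statement_date else None,
        )
        event = Event(
            seq=len(self.events),
            action=action,
            actor_id=actor_id,
            entity_kind=kind,
            entity_ref=ref,
            payload=payload,
        )
        self.events.append(event)
        return event

    def _require_editor(self, actor: Actor) -> None:
        if actor.role not in ("Editor", "Admin"):
            raise AuthorizationError(
                f"{actor.actor_id} ({actor.role}) may not decide submissions"
            )
        if actor.coi_statement_date is None:
            raise AuthorizationError(f"{actor.actor_id} has no conflict-of-interest statement")
        if self.today - actor.coi_statement_date > self.coi_window:
            raise AuthorizationError(
                f"{actor.actor_id}'s conflict-of-interest statement has expired"
            )

    # -- transitions -------------------------------------------------------

    def submit_evidence(
        self, item: EvidenceItem, actor_id: str
    ) -> tuple[EvidenceItem, list[str]]:
        """Submit a new evidence item, auto-creating gene/variant records.

        Returns the stored item plus any warnings (e.g. duplicate pending
        submission with identical identity fields).
        """
        warnings: list[str] = []
        identity = (
            item.gene_symbol,
            item.variant_name,
            item.source.source_id if item.source else None,
            item.evidence_type,
            item.disease_doid,
            tuple(item.drugs),
        )
        for other in self.corpus.evidence_items.values():
            other_identity = (
                other.gene_symbol,
                other.variant_name,
                other.source.source_id if other.source else None,
                other.evidence_type,
                other.disease_doid,
                tuple(other.drugs),
            )
            if other.moderation.state == "submitted" and other_identity == identity:
                warnings.append(f"duplicate of pending evidence item {other.eid}")
                break

        if item.gene_symbol and item.gene_symbol not in self.corpus.genes:
            self.corpus.genes[item.gene_symbol] = GeneRecord(gene_symbol=item.gene_symbol)
        if item.gene_symbol and item.variant_name and item.variant_id not in self.corpus.variants:
            self.corpus.variants[item.variant_id] = VariantRecord(
                gene_symbol=item.gene_symbol, variant_name=item.variant_name
            )
        item.moderation.state = "submitted"
        item.moderation.submitter_id = actor_id
        self.corpus.evidence_items[item.eid] = item
        payload = {k: v for k, v in item.to_dict().items() if k != "moderation"}
        self._record(
            "submit", actor_id, "evidence", item.eid,
            warnings=warnings, entity=payload,
        )
        return item, warnings

    def submit_assertion(self, assertion: Assertion, actor_id: str) -> Assertion:
        assertion.moderation.state = "submitted"
        assertion.moderation.submitter_id = actor_id
        self.corpus.assertions[assertion.aid] = assertion
        payload = {k: v for k, v in assertion.to_dict().items() if k != "moderation"}
        self._record("submit", actor_id, "assertion", assertion.aid, entity=payload)
        return assertion

    def accept(self, kind: str, ref: str, actor_id: str):
        """Editor acceptance; enforces COI, self-acceptance ban, assertion gate."""
        entity = self._entity(kind, ref)
        actor = self._actor(actor_id)
        self._require_editor(actor)
        if entity.moderation.submitter_id == actor_id:
            raise SelfAcceptanceError(
                f"{actor_id} may not accept their own submission {ref}"
            )
        if kind == "assertion":
            accepted = [
                eid
                for eid in entity.supporting_eids
                if eid in self.corpus.evidence_items
                and self.corpus.evidence_items[eid].moderation.state == "accepted"
            ]
            if not accepted:
                raise GateError(
                    f"assertion {ref} has no accepted supporting evidence item"
                )
        entity.moderation.state = "accepted"
        entity.moderation.decided_by = actor_id
        self._record("accept", actor_id, kind, ref)
        return entity

    def reject(self, kind: str, ref: str, actor_id: str, comment: str):
        """Rejection by an Editor/Admin or by the entity's own submitter."""
        if not comment or not comment.strip():
            raise CommentRequiredError("rejections require a rationale comment")
        entity = self._entity(kind, ref)
        actor = self._actor(actor_id)
        if entity.moderation.submitter_id != actor_id:
            self._require_editor(actor)
        entity.moderation.state = "rejected"
        entity.moderation.decided_by = actor_id
        entity.moderation.comments.append(
            {"actor_id": actor_id, "text": comment, "timestamp": len(self.events)}
        )
        self._record("reject", actor_id, kind, ref, comment=comment)
        if kind == "evidence":
            self._demote_orphaned_assertions(ref, actor_id)
        return entity

    def _demote_orphaned_assertions(self, rejected_eid: str, actor_id: str) -> None:
        """Accepted assertions losing their last accepted item fall back to
        submitted with an auto-flag, preserving the acceptance gate invariant."""
        for assertion in self.corpus.assertions.values():
            if assertion.moderation.state != "accepted":
                continue
            if rejected_eid not in assertion.supporting_eids:
                continue
            still_accepted = [
                eid
                for eid in assertion.supporting_eids
                if eid in self.corpus.evidence_items
                and self.corpus.evidence_items[eid].moderation.state == "accepted"
            ]
            if not still_accepted:
                assertion.moderation.state = "submitted"
                assertion.moderation.decided_by = None
                assertion.moderation.flagged = True
                assertion.moderation.comments.append(
                    {
                        "actor_id": actor_id,
                        "text": f"auto-demoted: last accepted evidence item {rejected_eid} was rejected",
                        "timestamp": len(self.events),
                    }
                )
                self._record(
                    "auto_demote", actor_id, "assertion", assertion.aid,
                    cause=rejected_eid,
                )

    def propose_revision(
        self,
        kind: str,
        ref: str,
        field_name: str,
        new_value,
        comment: str,
        actor_id: str,
    ) -> Revision:
        """Queue a field change; the entity is untouched until acceptance."""
        if not comment or not comment.strip():
            raise CommentRequiredError("suggested revisions require a comment")
        entity = self._entity(kind, ref)
        revisable = REVISABLE_FIELDS.get(kind, set())
        if field_name not in revisable:
            raise LifecycleError(f"field {field_name!r} is not revisable on {kind}")
        revision = Revision(
            field_name=field_name,
            old_value=getattr(entity, field_name),
            new_value=new_value,
            comment=comment,
            state="submitted",
            proposer_id=actor_id,
        )
        entity.moderation.revisions.append(revision)
        self._record(
            "propose_revision", actor_id, kind, ref,
            field=field_name, new_value=new_value, comment=comment,
        )
        return revision

    def accept_revision(self, kind: str, ref: str, revision_index: int, actor_id: str):
        """Apply a pending revision; returns the re-validation hook's input.

        Accepting one's own proposed revision is forbidden, mirroring the
        submission rule.
        """
        entity = self._entity(kind, ref)
        actor = self._actor(actor_id)
        self._require_editor(actor)
        try:
            revision = entity.moderation.revisions[revision_index]
        except IndexError:
            raise UnknownEntityError(f"no revision {revision_index} on {ref}") from None
        if revision.state != "submitted":
            raise LifecycleError(f"revision {revision_index} already {revision.state}")
        if revision.proposer_id == actor_id:
            raise SelfAcceptanceError(f"{actor_id} may not accept their own revision")
        setattr(entity, revision.field_name, revision.new_value)
        revision.state = "accepted"
        self._record(
            "accept_revision", actor_id, kind, ref, revision_index=revision_index
        )
        return entity

    def reject_revision(
        self, kind: str, ref: str, revision_index: int, actor_id: str, comment: str
    ):
        if not comment or not comment.strip():
            raise CommentRequiredError("rejections require a rationale comment")
        entity = self._entity(kind, ref)
        revision = entity.moderation.revisions[revision_index]
        if revision.state != "submitted":
            raise LifecycleError(f"revision {revision_index} already {revision.state}")
        if revision.proposer_id != actor_id:
            self._require_editor(self._actor(actor_id))
        revision.state = "rejected"
        self._record(
            "reject_revision", actor_id, kind, ref,
            revision_index=revision_index, comment=comment,
        )
        return entity

    def flag(self, kind: str, ref: str, actor_id: str, comment: str = ""):
        """Flag an entity for editor attention; idempotent."""
        entity = self._entity(kind, ref)
        entity.moderation.flagged = True
        if comment:
            entity.moderation.comments.append(
                {"actor_id": actor_id, "text": comment, "timestamp": len(self.events)}
            )
        self._record("flag", actor_id, kind, ref, comment=comment)
        return entity

    def resolve_flag(self, kind: str, ref: str, actor_id: str, comment: str):
        """Editor clears a flag with an explanatory comment."""
        if not comment or not comment.strip():
            raise CommentRequiredError("resolving a flag requires a comment")
        entity = self._entity(kind, ref)
        self._require_editor(self._actor(actor_id))
        entity.moderation.flagged = False
        entity.moderation.comments.append(
            {"actor_id": actor_id, "text": comment, "timestamp": len(self.events)}
        )
        self._record("resolve_flag", actor_id, kind, ref, comment=comment)
        return entity

    # -- event log ---------------------------------------------------------

    def dump_events(self) -> str:
        """Newline-delimited JSON event log."""
        return "\n".join(e.to_json() for e in self.events) + ("\n" if self.events else "")

    @classmethod
    def replay(
        cls,
        events: Iterable[Event],
        today: Optional[date] = None,
        coi_window_days: int = DEFAULT_COI_WINDOW_DAYS,
    ) -> "CurationEngine":
        """Rebuild a corpus by re-executing a self-contained event log.

        Submit events carry their entity payload and every event carries the
        acting actor's role/COI, so folding the same log always reproduces the
        same corpus.
        """
        engine = cls(Corpus(), today=today, coi_window_days=coi_window_days)
        for event in events:
            coi = event.payload.get("actor_coi")
            engine.actors[event.actor_id] = Actor(
                actor_id=event.actor_id,
                role=event.payload.get("actor_role", "Curator"),
                coi_statement_date=date.fromisoformat(coi) if coi else None,
            )
            if event.action == "submit" and event.entity_kind == "evidence":
                engine.submit_evidence(
                    EvidenceItem.from_dict(event.payload["entity"]), event.actor_id
                )
            elif event.action == "submit" and event.entity_kind == "assertion":
                engine.submit_assertion(
                    Assertion.from_dict(event.payload["entity"]), event.actor_id
                )
            elif event.action == "accept":
                engine.accept(event.entity_kind, event.entity_ref, event.actor_id)
            elif event.action == "reject":
                engine.reject(
                    event.entity_kind, event.entity_ref, event.actor_id,
                    event.payload.get("comment", "(replayed)"),
                )
            elif event.action == "propose_revision":
                engine.propose_revision(
                    event.entity_kind, event.entity_ref,
                    event.payload["field"], event.payload["new_value"],
                    event.payload["comment"], event.actor_id,
                )
            elif event.action == "accept_revision":
                engine.accept_revision(
                    event.entity_kind, event.entity_ref,
                    event.payload["revision_index"], event.actor_id,
                )
            elif event.action == "reject_revision":
                engine.reject_revision(
                    event.entity_kind, event.entity_ref,
                    event.payload["revision_index"], event.actor_id,
                    event.payload.get("comment", "(replayed)"),
                )
            elif event.action == "flag":
                engine.flag(
                    event.entity_kind, event.entity_ref, event.actor_id,
                    event.payload.get("comment", ""),
                )
            elif event.action == "resolve_flag":
                engine.resolve_flag(
                    event.entity_kind, event.entity_ref, event.actor_id,
                    event.payload.get("comment", "(replayed)"),
                )
            elif event.action == "auto_demote":
                pass  # side effect of the triggering rejection; re-derived
            else:
                raise LifecycleError(f"unknown event action {event.action!r}")
        return engine
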