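"""Concepts, Vocabularies and Mappings: the GDM vocabulary subsystem.

Every distinct ``(vocabulary, code)`` pair in a dataset receives a unique
numeric concept id.  Queries use the source codes; the Concepts table is a
lookup table, so ids need not agree across databases.  The Mappings table
stores directed relationships between concept ids (conventionally
``is_a`` for standardizations, e.g. a source sex coding onto a Sentinel
sex coding) without ever altering or discarding the source codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Default first id handed out by sequential assignment.
DEFAULT_ID_BASE = 100000001


class VocabularyError(Exception):
    pass


@dataclass(frozen=True)
class Vocabulary:
    id: str
    description: str = ""
    domain: str | None = None


@dataclass(frozen=True)
class Concept:
    id: int
    vocabulary_id: str
    concept_code: str
    concept_text: str = ""


@dataclass(frozen=True)
class Mapping:
    concept_id_1: int
    relationship_id: str
    concept_id_2: int


@dataclass
class ConceptStore:
    """In-memory store for concepts, vocabularies and mappings.

    Ids are either supplied explicitly (bulk loads of curated tables) or
    assigned sequentially in order of first appearance starting at
    ``id_base``; assignment is idempotent per ``(vocabulary, code)`` pair
    and therefore a bijection between pairs and ids.
    """

    id_base: int = DEFAULT_ID_BASE
    concepts: dict[int, Concept] = field(default_factory=dict)
    vocabularies: dict[str, Vocabulary] = field(default_factory=dict)
    mappings: list[Mapping] = field(default_factory=list)
    _by_pair: dict[tuple[str, str], int] = field(default_factory=dict)
    _mapping_keys: set[tuple[int, str, int]] = field(default_factory=set)
    next_id: int = 0

    def __post_init__(self) -> None:
        if self.next_id == 0:
            self.next_id = self.id_base

    # -- vocabularies -------------------------------------------------

    def register_vocabulary(
        self, vocabulary_id: str, description: str = "", domain: str | None = None
    ) -> Vocabulary:
        if vocabulary_id not in self.vocabularies:
            self.vocabularies[vocabulary_id] = Vocabulary(
                vocabulary_id, description, domain
            )
        return self.vocabularies[vocabulary_id]

    # -- concepts -----------------------------------------------------

    def load_concepts(self, records: list[Concept]) -> "ConceptStore":
        """Bulk-load concepts with explicit ids, preserved verbatim.

        Vocabularies are auto-registered and ``next_id`` advances past the
        maximum loaded id.  A duplicate id or duplicate (vocabulary, code)
        pair — within the batch or against the store — rejects the load
        before anything is applied.
        """
        seen_ids = set(self.concepts)
        seen_pairs = set(self._by_pair)
        for rec in records:
            pair = (rec.vocabulary_id, rec.concept_code)
            if rec.id in seen_ids:
                raise VocabularyError(f"duplicate concept id {rec.id}")
            if pair in seen_pairs:
                raise VocabularyError(f"duplicate (vocabulary, code) pair {pair}")
            seen_ids.add(rec.id)
            seen_pairs.add(pair)
        for rec in records:
            self.concepts[rec.id] = rec
            self._by_pair[(rec.vocabulary_id, rec.concept_code)] = rec.id
            self.register_vocabulary(rec.vocabulary_id)
            if rec.id >= self.next_id:
                self.next_id = rec.id + 1
        return self

    def get_or_assign(
        self, vocabulary_id: str, concept_code: str, concept_text: str = ""
    ) -> int:
        """Return the id for ``(vocabulary, code)``, assigning it if new."""
        if not vocabulary_id:
            raise VocabularyError("vocabulary_id must be non-empty")
        if concept_code == "" or concept_code is None:
            raise VocabularyError("concept_code must be non-empty")
        concept_code = str(concept_code)
        pair = (vocabulary_id, concept_code)
        if pair in self._by_pair:
            return self._by_pair[pair]
        cid = self.next_id
        self.next_id += 1
        self.concepts[cid] = Concept(cid, vocabulary_id, concept_code, concept_text)
        self._by_pair[pair] = cid
        self.register_vocabulary(vocabulary_id)
        return cid

    def lookup(self, vocabulary_id: str, concept_code: str) -> Concept | None:
        """The unique concept for ``(vocabulary, code)``, or ``None``.

        Not-found is a value, not an exception, so an ETL can branch on it
        cheaply and decide to assign.
        """
        cid = self._by_pair.get((vocabulary_id, str(concept_code)))
        return None if cid is None else self.concepts[cid]

    def __contains__(self, concept_id: int) -> bool:
        return concept_id in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)

    # -- mappings -----------------------------------------------------

    def add_mapping(
        self, concept_id_1: int, relationship_id: str, concept_id_2: int
    ) -> None:
        for cid in (concept_id_1, concept_id_2):
            if cid not in self.concepts:
                raise VocabularyError(f"unknown concept id {cid}")
        key = (concept_id_1, relationship_id, concept_id_2)
        if key in self._mapping_keys:
            return  # reloading a superset never changes existing results
        self._mapping_keys.add(key)
        self.mappings.append(Mapping(*key))

    def map_concepts(
        self,
        source_id: int,
        relationship_id: str,
        target_vocabulary: str | None = None,
    ) -> set[int]:
        """All targets of ``source_id`` under ``relationship_id``.

        Optionally restricted to targets in ``target_vocabulary``.  Empty
        set when no mapping exists (callers fall back to the source
        concept — mapping never alters the stored codes).
        """
        if source_id not in self.concepts:
            raise VocabularyError(f"unknown concept id {source_id}")
        out = set()
        for m in self.mappings:
            if m.concept_id_1 == source_id and m.relationship_id == relationship_id:
                if (
                    target_vocabulary is None
                    or self.concepts[m.concept_id_2].vocabulary_id == target_vocabulary
                ):
                    out.add(m.concept_id_2)
        return out

    # -- table views --------------------------------------------------

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """The concepts / vocabularies / mappings tables as DataFrames."""
        concepts = pd.DataFrame(
            [
                (c.id, c.vocabulary_id, c.concept_code, c.concept_text)
                for c in sorted(self.concepts.values(), key=lambda c: c.id)
            ],
            columns=["id", "vocabulary_id", "concept_code", "concept_text"],
        )
        vocabularies = pd.DataFrame(
            [
                (v.id, v.description, v.domain)
                for v in sorted(self.vocabularies.values(), key=lambda v: v.id)
            ],
            columns=["id", "description", "domain"],
        )
        mappings = pd.DataFrame(
            sorted((m.concept_id_1, m.relationship_id, m.concept_id_2)
                   for m in self.mappings),
            columns=["concept_id_1", "relationship_id", "concept_id_2"],
        )
        return {
            "concepts": concepts,
            "vocabularies": vocabularies,
            "mappings": mappings,
        }

    @classmethod
    def from_frames(cls, frames: dict[str, pd.DataFrame],
                    id_base: int = DEFAULT_ID_BASE) -> "ConceptStore":
        store = cls(id_base=id_base)
        for _, row in frames.get("vocabularies", pd.DataFrame()).iterrows():
            domain = row.get("domain")
            store.register_vocabulary(
                str(row["id"]),
                "" if pd.isna(row.get("description")) else str(row["description"]),
                None if pd.isna(domain) else str(domain),
            )
        con = frames.get("concepts")
        if con is not None and len(con):
            store.load_concepts(
                [
                    Concept(
                        int(r["id"]), str(r["vocabulary_id"]),
                        str(r["concept_code"]),
                        "" if pd.isna(r["concept_text"]) else str(r["concept_text"]),
                    )
                    for _, r in con.iterrows()
                ]
            )
        mp = frames.get("mappings")
        if mp is not None and len(mp):
            for _, r in mp.iterrows():
                store.add_mapping(
                    int(r["concept_id_1"]), str(r["relationship_id"]),
                    int(r["concept_id_2"]),
                )
        return store


# ---------------------------------------------------------------------------
# Printed reference fixtures
#
# Two small curated vocabularies ship with the package: the NAACCR tumor
# grade codes used by SEER registries, and the demonstration mapping of the
# SynPUF sex/race codings onto the Sentinel sex / race / hispanic codings.

#: NAACCR tumor grade: (id, code, descriptive text).
SEER_GRADE_CONCEPTS: tuple[tuple[int, str, str], ...] = (
    (100010943, "1", "Grade I; grade i; grade 1; well differentiated; "
                     "differentiated, NOS"),
    (100010944, "2", "Grade II; grade ii; grade 2; moderately differentiated; "
                     "moderately well differentiated; intermediate differentiation"),
    (100010945, "3", "Grade III; grade iii; grade 3; poorly differentiated; "
                     "differentiated"),
    (100010946, "4", "Grade IV; grade iv; grade 4; undifferentiated; anaplastic"),
    (100010947, "5", "T-cell; T-precursor"),
    (100010948, "6", "B-cell; Pre-B; B-Precursor"),
    (100010949, "7", "Null cell; Non T-non B;"),
    (100010950, "8", "N K cell (natural killer cell)"),
    (100010951, "9", "cell type not determined, not stated or not applicable"),
)


def seer_grade_concepts() -> list[Concept]:
    """The nine NAACCR tumor-grade concepts (vocabulary ``naaccr_grade``)."""
    return [
        Concept(cid, "naaccr_grade", code, text)
        for cid, code, text in SEER_GRADE_CONCEPTS
    ]


#: SynPUF demographic codings and their Sentinel counterparts:
#: (id, vocabulary, code, text).
_SYNPUF_SENTINEL_CONCEPTS: tuple[tuple[int, str, str, str], ...] = (
    (100000001, "synpuf_sex", "1", "Male"),
    (100000002, "synpuf_sex", "2", "Female"),
    (100000003, "synpuf_race", "1", "White"),
    (100000004, "synpuf_race", "2", "Black"),
    (100000005, "synpuf_race", "3", "Others"),
    (100000006, "synpuf_race", "5", "Hispanic"),
    (100000092, "sentinel_sex", "F", "Female"),
    (100000093, "sentinel_sex", "M", "Male"),
    (100000095, "sentinel_hispanic", "N", "Not Applicable"),
    (100000097, "sentinel_hispanic", "Y", "Yes"),
    (100000098, "sentinel_race", "0", "Unknown"),
    (100000101, "sentinel_race", "3", "Black or African American"),
    (100000103, "sentinel_race", "5", "White"),
)

#: ``is_a`` standardization edges from SynPUF codes to Sentinel codes.
_SYNPUF_SENTINEL_MAPPINGS: tuple[tuple[int, str, int], ...] = (
    (100000002, "is_a", 100000092),  # sex 2 (Female)  -> sentinel_sex F
    (100000001, "is_a", 100000093),  # sex 1 (Male)    -> sentinel_sex M
    (100000003, "is_a", 100000095),  # race 1 (White)    -> hispanic N
    (100000004, "is_a", 100000095),  # race 2 (Black)    -> hispanic N
    (100000005, "is_a", 100000095),  # race 3 (Others)   -> hispanic N
    (100000006, "is_a", 100000097),  # race 5 (Hispanic) -> hispanic Y
    (100000005, "is_a", 100000098),  # race 3 (Others)   -> sentinel_race 0
    (100000006, "is_a", 100000098),  # race 5 (Hispanic) -> sentinel_race 0
    (100000004, "is_a", 100000101),  # race 2 (Black)    -> sentinel_race 3
    (100000003, "is_a", 100000103),  # race 1 (White)    -> sentinel_race 5
)


def synpuf_sentinel_concepts() -> list[Concept]:
    """SynPUF sex/race concepts plus the Sentinel target concepts."""
    return [Concept(*row) for row in _SYNPUF_SENTINEL_CONCEPTS]


def load_synpuf_sentinel_mappings(store: ConceptStore) -> ConceptStore:
    """Load the SynPUF→Sentinel demographic concepts and ``is_a`` mappings.

    Concepts whose (vocabulary, code) pair is already in the store keep
    their existing ids; mappings are expressed against whatever ids the
    pairs resolve to, so the load composes with sequential assignment.
    """
    by_pair = {c.id: c for c in synpuf_sentinel_concepts()}
    fresh = [
        c for c in by_pair.values()
        if store.lookup(c.vocabulary_id, c.concept_code) is None
    ]
    store.load_concepts(fresh)
    for cid1, rel, cid2 in _SYNPUF_SENTINEL_MAPPINGS:
        c1, c2 = by_pair[cid1], by_pair[cid2]
        store.add_mapping(
            store.lookup(c1.vocabulary_id, c1.concept_code).id,
            rel,
            store.lookup(c2.vocabulary_id, c2.concept_code).id,
        )
    return store
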