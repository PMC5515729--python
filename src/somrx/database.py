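"""The two fingerprint databases: all substrate atoms, and reaction centers.

The substrate database aggregates the layered fingerprint of *every* heavy
atom of every curated substrate; the reaction-center database aggregates the
fingerprints of the annotated SOM atoms only, each key carrying the multiset
of reaction-pattern ids observed for that environment.  Counts are
occurrence-weighted: the same environment seen in ten substrates contributes
ten, and a query hit adds the stored occurrence count to the m / n totals.

Because every reaction center is a substrate atom, the center database is
contained in the substrate database key-for-key with no larger counts, which
guarantees n <= m for every query.

Persistence is JSON-lines plus a manifest with a SHA-256 content hash;
loading verifies the hash.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .chem_io import PatternRecord, ReactionRecord
from .fingerprint import (DEFAULT_ALPHABET, N_LAYERS, AtomTypeAlphabet,
                          FingerprintMatrix, deserialize_counts,
                          molecule_fingerprints)
from .similarity import SimilarityParams, is_similar

PREFIX_DEPTH = 3  # hash-bucket depth used for fast retrieval


class CorruptDatabaseError(RuntimeError):
    """Stored database content does not match its manifest hash."""


class AlphabetMismatchError(RuntimeError):
    """Query fingerprint was built with a different alphabet version."""


@dataclass
class SubstrateEntry:
    fingerprint_key: str
    occurrence_count: int = 0


@dataclass
class ReactionCenterEntry:
    fingerprint_key: str
    occurrence_count: int = 0
    pattern_counts: Counter = field(default_factory=Counter)


def _prefix_key(key: str, depth: int = PREFIX_DEPTH) -> str:
    return "|".join(key.split("|")[:depth])


@dataclass
class FingerprintDatabasePair:
    substrate_db: dict[str, SubstrateEntry] = field(default_factory=dict)
    center_db: dict[str, ReactionCenterEntry] = field(default_factory=dict)
    alphabet_version: str = DEFAULT_ALPHABET.version
    n_layers: int = N_LAYERS
    build_manifest: dict = field(default_factory=dict)
    # prefix (layers 0..2) -> substrate keys, for fast exact-match retrieval
    _prefix_index: dict[str, list[str]] = field(default_factory=dict, repr=False)
    _matrices: dict = field(default_factory=dict, repr=False)

    def _matrix(self, key: str, alphabet: AtomTypeAlphabet) -> FingerprintMatrix:
        fp = self._matrices.get(key)
        if fp is None:
            fp = FingerprintMatrix(
                deserialize_counts(key, self.n_layers, alphabet.width),
                root_atom=-1, alphabet=alphabet)
            self._matrices[key] = fp
        return fp

    def _rebuild_index(self) -> None:
        self._prefix_index.clear()
        for key in self.substrate_db:
            self._prefix_index.setdefault(_prefix_key(key), []).append(key)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for key in sorted(self.substrate_db):
            e = self.substrate_db[key]
            h.update(f"S\t{key}\t{e.occurrence_count}\n".encode())
        for key in sorted(self.center_db):
            e = self.center_db[key]
            pats = ",".join(f"{p}={c}" for p, c in sorted(e.pattern_counts.items()))
            h.update(f"C\t{key}\t{e.occurrence_count}\t{pats}\n".encode())
        return h.hexdigest()


def build_databases(records: Sequence[ReactionRecord],
                    annotations: Sequence,
                    patterns: Sequence[PatternRecord],
                    alphabet: AtomTypeAlphabet = DEFAULT_ALPHABET,
                    n_layers: int = N_LAYERS) -> FingerprintDatabasePair:
    """Aggregate substrate-atom and reaction-center fingerprints.

    Every heavy atom of every record's substrate increments the substrate
    database; every annotated SOM atom increments the center database under
    the record's pattern id (or a per-record pseudo-id when the record has
    none, so unpatterned centers still count toward n).
    """
    by_id = {rec.record_id: rec for rec in records}
    db = FingerprintDatabasePair(alphabet_version=alphabet.version,
                                 n_layers=n_layers)
    for ann in annotations:
        if ann.record_id not in by_id:
            raise KeyError(f"annotation references unknown record {ann.record_id!r}")

    for rec in records:
        fps = molecule_fingerprints(rec.substrate(), n_layers, alphabet,
                                    molecule_id=rec.record_id)
        for fp in fps:
            key = fp.key()
            entry = db.substrate_db.setdefault(key, SubstrateEntry(key))
            entry.occurrence_count += 1

    for ann in annotations:
        rec = by_id[ann.record_id]
        pattern_id = rec.pattern_id or f"@{ann.method}:{ann.record_id}"
        fps = molecule_fingerprints(rec.substrate(), n_layers, alphabet,
                                    molecule_id=rec.record_id)
        for idx in ann.som_atoms:
            if not 0 <= idx < len(fps):
                raise KeyError(
                    f"annotation {ann.record_id}: SOM index {idx} out of range")
            key = fps[idx].key()
            entry = db.center_db.setdefault(key, ReactionCenterEntry(key))
            entry.occurrence_count += 1
            entry.pattern_counts[pattern_id] += 1

    db._rebuild_index()
    db.build_manifest = {
        "alphabet_version": alphabet.version,
        "n_layers": n_layers,
        "n_records": len(records),
        "n_annotations": len(annotations),
        "n_substrate_keys": len(db.substrate_db),
        "n_center_keys": len(db.center_db),
        "content_hash": db.content_hash(),
    }
    return db


def query(db: FingerprintDatabasePair, fp: FingerprintMatrix,
          params: SimilarityParams | None = None
          ) -> tuple[list[SubstrateEntry], list[ReactionCenterEntry]]:
    """All similar entries from both databases (occurrence-weighted hits).

    Uses the layer-0..2 prefix index when the exact-match depth allows it;
    results are identical to a linear scan by construction.
    """
    params = params or SimilarityParams(n_layers=db.n_layers)
    if fp.alphabet.version != db.alphabet_version:
        raise AlphabetMismatchError(
            f"query alphabet {fp.alphabet.version!r} != db {db.alphabet_version!r}")
    if params.exact_depth >= PREFIX_DEPTH:
        candidates: Iterable[str] = db._prefix_index.get(
            _prefix_key(fp.key()), ())
    else:
        candidates = db.substrate_db.keys()
    m_hits: list[SubstrateEntry] = []
    n_hits: list[ReactionCenterEntry] = []
    for key in sorted(candidates):  # deterministic across build orders
        if is_similar(fp, db._matrix(key, fp.alphabet), params):
            m_hits.append(db.substrate_db[key])
            center = db.center_db.get(key)
            if center is not None:
                n_hits.append(center)
    return m_hits, n_hits


def save(db: FingerprintDatabasePair, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with (path / "substrate.jsonl").open("w", encoding="utf-8") as fh:
        for key in sorted(db.substrate_db):
            e = db.substrate_db[key]
            fh.write(json.dumps({"key": key, "count": e.occurrence_count}) + "\n")
    with (path / "centers.jsonl").open("w", encoding="utf-8") as fh:
        for key in sorted(db.center_db):
            e = db.center_db[key]
            fh.write(json.dumps({"key": key, "count": e.occurrence_count,
                                 "patterns": dict(sorted(e.pattern_counts.items()))})
                     + "\n")
    with (path / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(db.build_manifest or {
            "alphabet_version": db.alphabet_version,
            "n_layers": db.n_layers,
            "content_hash": db.content_hash(),
        }, fh, indent=1, sort_keys=True)


def load(path: str | Path) -> FingerprintDatabasePair:
    path = Path(path)
    try:
        manifest = json.loads((path / "manifest.json").read_text())
        db = FingerprintDatabasePair(
            alphabet_version=manifest.get("alphabet_version",
                                          DEFAULT_ALPHABET.version),
            n_layers=int(manifest.get("n_layers", N_LAYERS)),
            build_manifest=manifest)
        with (path / "substrate.jsonl").open(encoding="utf-8") as fh:
            for line in fh:
                rec = json.loads(line)
                db.substrate_db[rec["key"]] = SubstrateEntry(
                    rec["key"], int(rec["count"]))
        with (path / "centers.jsonl").open(encoding="utf-8") as fh:
            for line in fh:
                rec = json.loads(line)
                db.center_db[rec["key"]] = ReactionCenterEntry(
                    rec["key"], int(rec["count"]),
                    Counter({k: int(v) for k, v in rec["patterns"].items()}))
    except (OSError, ValueError, KeyError) as exc:
        raise CorruptDatabaseError(f"cannot load database from {path}: {exc}") from exc
    expected = manifest.get("content_hash")
    if expected is not None and db.content_hash() != expected:
        raise CorruptDatabaseError(f"content hash mismatch in {path}")
    db._rebuild_index()
    return db
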