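"""Sequence-similarity decisions: consensus confirmation and family origin.

Two interchangeable evidence backends feed the same decision logic:

* ``hit_table`` -- pre-computed 12-column BLAST tabular files, one per
  reference set, with hits qualifying when E-value <= the cutoff
  (1e-10, inclusive);
* ``kmer`` -- a built-in canonical k-mer containment index over
  reference FASTAs.  A query "hits" a reference collection when the
  fraction of its distinct canonical k-mers found in the collection
  reaches ``kmer_containment_min``.  Under a substitution-only
  divergence model at per-site rate p the expected containment is
  ~(1-p)^k, so k=21 with a 0.10 floor separates within-family (<~10%
  diverged) from between-family (>~30% diverged) relationships.

"Dual" search means querying each reference collection independently
(any qualifying hit counts); unigenes hitting both families are left
unassigned-to-species ("both"), matching conserved orthologs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import HomologyHit, RunConfig, UnigeneRecord

_CODE = np.full(256, 255, dtype=np.uint8)
for _c, _v in zip(b"ACGT", range(4)):
    _CODE[_c] = _v
for _c, _v in zip(b"acgt", range(4)):
    _CODE[_c] = _v


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Canonical (strand-insensitive) 2-bit packed k-mers of *seq*.

    Windows containing non-ACGT characters are dropped.
    """
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = _CODE[raw]
    if codes.size < k:
        return np.empty(0, dtype=np.uint64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win < 4).all(axis=1)
    win = win[valid].astype(np.uint64)
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    fwd = win @ powers
    rc = (np.uint64(3) - win[:, ::-1]) @ powers
    return np.minimum(fwd, rc)


def _distinct_sorted(kmers: np.ndarray) -> np.ndarray:
    if kmers.size == 0:
        return kmers
    s = np.sort(kmers)
    keep = np.empty(s.size, dtype=bool)
    keep[0] = True
    np.not_equal(s[1:], s[:-1], out=keep[1:])
    return s[keep]


@dataclass
class KmerIndex:
    """Sorted array of the distinct canonical k-mers of a reference set."""

    k: int
    kmers: np.ndarray  # sorted uint64

    @classmethod
    def build(cls, records: Iterable[UnigeneRecord], k: int) -> "KmerIndex":
        parts = [_kmer_codes(r.seq, k) for r in records]
        allk = _distinct_sorted(np.concatenate(parts)) if parts \
            else np.empty(0, np.uint64)
        return cls(k=k, kmers=allk)

    def __len__(self) -> int:
        return int(self.kmers.size)


def kmer_containment(query: str, index: KmerIndex) -> float:
    """Fraction of the query's distinct canonical k-mers present in the
    reference index."""
    if len(query) < index.k:
        raise ValueError(f"query shorter than k={index.k}")
    q = _distinct_sorted(_kmer_codes(query, index.k))
    return _containment_of(q, index)


def _containment_of(query_kmers: np.ndarray, index: KmerIndex) -> float:
    if query_kmers.size == 0:
        raise ValueError("query contains no valid k-mer window")
    if len(index.kmers) == 0:
        return 0.0
    pos = np.clip(np.searchsorted(index.kmers, query_kmers), 0, len(index.kmers) - 1)
    found = int((index.kmers[pos] == query_kmers).sum())
    return found / query_kmers.size


def call_hit(containment: float, config: RunConfig) -> bool:
    """Containment-threshold analogue of the E-value cutoff."""
    if not (0.0 <= containment <= 1.0):
        raise ValueError("containment must be in [0, 1]")
    return containment >= config.kmer_containment_min


def scan_kmer(
    records: Sequence[UnigeneRecord],
    references: Mapping[str, KmerIndex],
    config: RunConfig,
) -> dict[str, list[HomologyHit]]:
    """Query every record against every reference index; emit surrogate
    hits (evalue 0) for calls that pass the containment floor.

    ``pct_identity`` is back-estimated from containment as
    100 * c^(1/k), the substitution-only inversion of (1-p)^k.
    """
    out: dict[str, list[HomologyHit]] = {r.id: [] for r in records}
    ks = {idx.k for idx in references.values()}
    if len(ks) > 1:
        raise ValueError(f"reference indices disagree on k: {sorted(ks)}")
    query_kmers = {
        r.id: _distinct_sorted(_kmer_codes(r.seq, config.kmer_k)) for r in records
    }
    for label, index in references.items():
        for rec in records:
            c = _containment_of(query_kmers[rec.id], index)
            if call_hit(c, config):
                ident = 100.0 * c ** (1.0 / index.k)
                out[rec.id].append(HomologyHit(
                    query_id=rec.id, subject_id=f"{label}:index",
                    pct_identity=ident, align_len=rec.length,
                    evalue=0.0, bitscore=c, refset=label,
                ))
    return out


def _qualifying(hits: Iterable[HomologyHit], config: RunConfig) -> list[HomologyHit]:
    return [h for h in hits if h.evalue <= config.evalue_cutoff]


def consensus_filter(
    candidate_ids: set[str],
    evidence: Mapping[str, Sequence[HomologyHit]],
    config: RunConfig,
) -> set[str]:
    """Keep ids with >= 1 qualifying hit in >= 1 species-level reference
    set (union semantics over the reference collections)."""
    refsets = {h.refset for hits in evidence.values() for h in hits}
    if not refsets and not any(evidence.values()):
        # an empty evidence map is allowed only when it covers no refs at all
        raise ValueError("consensus_filter requires a non-empty refset collection")
    retained = set()
    for uid in candidate_ids:
        if _qualifying(evidence.get(uid, ()), config):
            retained.add(uid)
    return retained


@dataclass(frozen=True)
class FamilyAssignment:
    """Dual-family homology verdict for one unigene."""

    unigene_id: str
    hits_family_a: bool  # parasite-family reference collection
    hits_family_b: bool  # host-family reference collection
    verdict: str  # A_only | B_only | both | neither

    def __post_init__(self):
        expected = {
            (True, False): "A_only",
            (False, True): "B_only",
            (True, True): "both",
            (False, False): "neither",
        }[(self.hits_family_a, self.hits_family_b)]
        if self.verdict != expected:
            raise ValueError(f"verdict {self.verdict!r} inconsistent with hit flags")


def _verdict(a: bool, b: bool) -> str:
    if a and b:
        return "both"
    if a:
        return "A_only"
    if b:
        return "B_only"
    return "neither"


def assign_family(
    unigene_id: str,
    hits: Sequence[HomologyHit],
    config: RunConfig,
    family_a: str,
    family_b: str,
) -> FamilyAssignment:
    """Dual-search verdict from family-labelled hits.

    ``family_a`` is the parasite-side family label, ``family_b`` the
    host-side one; a unigene qualifying against both is "both" (too
    homologous to place), against neither is "neither" (low similarity,
    dropped from classification).
    """
    known = {family_a, family_b}
    for h in hits:
        if h.refset not in known:
            raise ValueError(f"hit for {unigene_id!r} has unknown refset {h.refset!r}")
    qual = _qualifying(hits, config)
    a = any(h.refset == family_a for h in qual)
    b = any(h.refset == family_b for h in qual)
    return FamilyAssignment(unigene_id, a, b, _verdict(a, b))


def assign_families(
    ids: Iterable[str],
    evidence: Mapping[str, Sequence[HomologyHit]],
    config: RunConfig,
    family_a: str,
    family_b: str,
) -> dict[str, FamilyAssignment]:
    return {
        uid: assign_family(uid, evidence.get(uid, ()), config, family_a, family_b)
        for uid in ids
    }
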