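"""Core mobile-mRNA classification: Venn partition, directional calls,
haustorium mediation and the transfer-summary arithmetic.

Candidates for mobility are the unigenes detected in both the parasite
stem (CD) and the parasitized host root (HC).  The parasite-free host
root (HA) splits them into an HA-exclusive region (absent from the
unparasitized host, hence mostly parasite-origin transcripts that moved
CD->HC) and an HA-containing region (present in the healthy host too,
hence mostly host transcripts that moved HC->CD).  The *direction* of
each candidate is decided not by its Venn region but by its dual-family
homology verdict: a parasite-family-only verdict means CD->HC, a
host-family-only verdict HC->CD, hits to both families are ambiguous
(conserved orthologs), and no-hit candidates stay unassigned and are
excluded from mobile totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .expression import PresenceSet
from .homology import FamilyAssignment

DIRECTIONS = ("CD_to_HC", "HC_to_CD", "ambiguous", "unassigned", "non_mobile")

_VERDICT_TO_DIRECTION = {
    "A_only": "CD_to_HC",   # parasite-family origin
    "B_only": "HC_to_CD",   # host-family origin
    "both": "ambiguous",
    "neither": "unassigned",
}


def _round2(x: float) -> float:
    return float(round(x, 2))


@dataclass(frozen=True)
class VennPartition:
    """The 7-region partition of the CD/HC/HA presence sets."""

    regions: Mapping[str, frozenset[str]]

    _KEYS = (
        "CD_only", "HC_only", "HA_only",
        "CD_HC", "CD_HA", "HC_HA", "CD_HC_HA",
    )

    def __post_init__(self):
        missing = set(self._KEYS) - set(self.regions)
        if missing:
            raise ValueError(f"missing Venn regions: {sorted(missing)}")

    @property
    def ha_exclusive(self) -> frozenset[str]:
        """HC n CD \\ HA — candidates absent from the healthy host root."""
        return self.regions["CD_HC"]

    @property
    def ha_containing(self) -> frozenset[str]:
        """HC n CD n HA — candidates present in the healthy host root too."""
        return self.regions["CD_HC_HA"]

    @property
    def candidates(self) -> frozenset[str]:
        return self.ha_exclusive | self.ha_containing

    def counts(self) -> dict[str, int]:
        return {k: len(self.regions[k]) for k in self._KEYS}


def venn_partition(presence: Mapping[str, PresenceSet]) -> VennPartition:
    """Exact set-algebra partition of the CD, HC and HA presence sets."""
    for group in ("CD", "HC", "HA"):
        if group not in presence:
            raise ValueError(f"missing presence set for group {group!r}")
    cd = set(presence["CD"].present_ids)
    hc = set(presence["HC"].present_ids)
    ha = set(presence["HA"].present_ids)
    regions = {
        "CD_only": cd - hc - ha,
        "HC_only": hc - cd - ha,
        "HA_only": ha - cd - hc,
        "CD_HC": (cd & hc) - ha,
        "CD_HA": (cd & ha) - hc,
        "HC_HA": (hc & ha) - cd,
        "CD_HC_HA": cd & hc & ha,
    }
    return VennPartition({k: frozenset(v) for k, v in regions.items()})


@dataclass
class MobilityCall:
    """Per-unigene verdict of the classification stage."""

    unigene_id: str
    candidate_region: str  # HA_exclusive | HA_containing | non_candidate
    family_verdict: str    # A_only | B_only | both | neither | ("" for non-candidates)
    direction: str         # CD_to_HC | HC_to_CD | ambiguous | unassigned | non_mobile
    in_haustorium: bool = False


def classify_mobility(
    partition: VennPartition,
    assignments: Mapping[str, FamilyAssignment],
    all_ids: Optional[Sequence[str]] = None,
) -> list[MobilityCall]:
    """Directional calls for every unigene.

    Candidates (HC n CD) take their direction from the family verdict;
    every candidate must have an assignment.  Non-candidate ids (the
    rest of *all_ids*, or of the Venn universe when *all_ids* is None)
    are non_mobile.
    """
    calls: list[MobilityCall] = []
    region_of: dict[str, str] = {}
    for uid in partition.ha_exclusive:
        region_of[uid] = "HA_exclusive"
    for uid in partition.ha_containing:
        region_of[uid] = "HA_containing"

    universe = list(all_ids) if all_ids is not None else sorted(
        set().union(*partition.regions.values())
    )
    seen = set()
    for uid in universe:
        if uid in seen:
            raise ValueError(f"duplicate unigene id {uid!r}")
        seen.add(uid)
        region = region_of.get(uid)
        if region is None:
            calls.append(MobilityCall(uid, "non_candidate", "", "non_mobile"))
            continue
        if uid not in assignments:
            raise ValueError(f"candidate {uid!r} lacks a family assignment")
        verdict = assignments[uid].verdict
        calls.append(MobilityCall(uid, region, verdict, _VERDICT_TO_DIRECTION[verdict]))
    missing = set(region_of) - seen
    if missing:
        raise ValueError(f"candidates outside the id universe: {sorted(missing)[:3]}")
    return calls


def haustorium_mediation(
    calls: Sequence[MobilityCall],
    hi_presence: PresenceSet,
) -> tuple[Optional[float], Optional[float]]:
    """Fraction of mobile calls (per direction) present at the
    haustorial interface; ``None`` when a direction has no calls.

    Also sets the ``in_haustorium`` flag on every call.
    """
    n = {"CD_to_HC": 0, "HC_to_CD": 0}
    k = {"CD_to_HC": 0, "HC_to_CD": 0}
    for call in calls:
        call.in_haustorium = call.unigene_id in hi_presence
        if call.direction in n:
            n[call.direction] += 1
            k[call.direction] += call.in_haustorium
    frac_cd = k["CD_to_HC"] / n["CD_to_HC"] if n["CD_to_HC"] else None
    frac_ha = k["HC_to_CD"] / n["HC_to_CD"] if n["HC_to_CD"] else None
    return frac_cd, frac_ha


@dataclass
class TransferSummary:
    """Headline arithmetic of a run; ratio fields are None when undefined.

    Percentages and fold ratios are rounded to 2 decimals; the Venn
    outnumber ratio to the nearest integer.
    """

    n_CD_to_HC: int
    n_HC_to_CD: int
    n_ambiguous: int
    n_unassigned: int
    n_candidates: int
    n_total_mobile: int
    fold_bias: Optional[float]
    pct_of_destination_HC: Optional[float]
    pct_of_source_CD: Optional[float]
    pct_of_source_HC: Optional[float]
    pct_of_destination_CD: Optional[float]
    haustorium_pct_CD_origin: Optional[float]
    haustorium_pct_HA_origin: Optional[float]
    venn_outnumber_ratio: Optional[int]

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _pct(num: Optional[float], den: Optional[float]) -> Optional[float]:
    if num is None or not den:
        return None
    return _round2(100.0 * num / den)


def summarize_from_tallies(t: Mapping[str, float]) -> TransferSummary:
    """Transfer summary from raw tallies (counts, region sizes and
    group totals), as used for worked-example arithmetic.

    Expected keys: n_CD_to_HC, n_HC_to_CD, n_ambiguous, n_unassigned,
    n_candidates, n_HA_exclusive, n_HA_CD_not_HC, n_in_HI_CD_origin,
    n_in_HI_HA_origin, and the four denominators
    n_unigenes_{HC_dest,CD_source,HC_source,CD_dest}.  Missing
    denominators yield None fields.
    """
    get = lambda k: t.get(k)
    n_cd = int(t["n_CD_to_HC"])
    n_hc = int(t["n_HC_to_CD"])
    total = n_cd + n_hc
    fold = _round2(n_cd / n_hc) if n_hc else None
    ha_excl = get("n_HA_exclusive")
    ha_cd = get("n_HA_CD_not_HC")
    outnumber = int(round(ha_excl / ha_cd)) if ha_excl and ha_cd else None
    return TransferSummary(
        n_CD_to_HC=n_cd,
        n_HC_to_CD=n_hc,
        n_ambiguous=int(t.get("n_ambiguous", 0)),
        n_unassigned=int(t.get("n_unassigned", 0)),
        n_candidates=int(t.get("n_candidates", 0)),
        n_total_mobile=total,
        fold_bias=fold,
        pct_of_destination_HC=_pct(n_cd, get("n_unigenes_HC_dest")),
        pct_of_source_CD=_pct(n_cd, get("n_unigenes_CD_source")),
        pct_of_source_HC=_pct(n_hc, get("n_unigenes_HC_source")),
        pct_of_destination_CD=_pct(n_hc, get("n_unigenes_CD_dest")),
        haustorium_pct_CD_origin=_pct(get("n_in_HI_CD_origin"), n_cd),
        haustorium_pct_HA_origin=_pct(get("n_in_HI_HA_origin"), n_hc),
        venn_outnumber_ratio=outnumber,
    )


def summarize_transfer(
    calls: Sequence[MobilityCall],
    partition: VennPartition,
    presence: Mapping[str, PresenceSet],
    hi_presence: PresenceSet,
) -> TransferSummary:
    """Compute the transfer summary from classification outputs.

    Destination/source percentages use the CD and HC presence-set
    sizes as denominators for both roles (in a single-run pipeline the
    same detected set plays source and destination).
    """
    by_dir = {d: 0 for d in DIRECTIONS}
    in_hi = {"CD_to_HC": 0, "HC_to_CD": 0}
    for call in calls:
        by_dir[call.direction] += 1
        if call.direction in in_hi and call.unigene_id in hi_presence:
            in_hi[call.direction] += 1
    tallies = {
        "n_CD_to_HC": by_dir["CD_to_HC"],
        "n_HC_to_CD": by_dir["HC_to_CD"],
        "n_ambiguous": by_dir["ambiguous"],
        "n_unassigned": by_dir["unassigned"],
        "n_candidates": len(partition.candidates),
        "n_HA_exclusive": len(partition.ha_exclusive),
        "n_HA_CD_not_HC": len(partition.regions["CD_HA"]),
        "n_in_HI_CD_origin": in_hi["CD_to_HC"],
        "n_in_HI_HA_origin": in_hi["HC_to_CD"],
        "n_unigenes_HC_dest": len(presence["HC"]),
        "n_unigenes_CD_source": len(presence["CD"]),
        "n_unigenes_HC_source": len(presence["HC"]),
        "n_unigenes_CD_dest": len(presence["CD"]),
    }
    return summarize_from_tallies(tallies)
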