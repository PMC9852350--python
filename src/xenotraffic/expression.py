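"""FPKM conversion, per-group presence/absence calls and summaries.

Presence is the pipeline's detection primitive: a unigene counts as
expressed in a tissue group when its FPKM reaches the threshold (0.3 by
default, inclusive) in at least ``min_replicates_present`` replicates
of that group.  The single-replicate haustorial-interface group uses
the same rule over its one library.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, RunConfig, SampleDesign


@dataclass(frozen=True)
class PresenceSet:
    """Ids called present in one tissue group, with the rule that made them."""

    group: str
    present_ids: frozenset[str]
    rule: tuple[float, int]  # (fpkm_threshold, min_replicates_present)

    def __contains__(self, unigene_id: str) -> bool:
        return unigene_id in self.present_ids

    def __len__(self) -> int:
        return len(self.present_ids)


def compute_fpkm(counts: ExpressionMatrix, lengths: Mapping[str, int]) -> ExpressionMatrix:
    """Fragments per kilobase per million mapped fragments.

    fpkm[i, L] = count[i, L] * 1e9 / (length_i * total_count_L), using
    the full transcript length (no effective-length correction, since
    read-level modelling is out of scope here).
    """
    if counts.value_kind != "count":
        raise ValueError("compute_fpkm expects a count matrix")
    missing = [i for i in counts.unigene_ids if i not in lengths]
    if missing:
        raise ValueError(f"missing transcript lengths for {len(missing)} unigenes, "
                         f"e.g. {missing[:3]}")
    totals = counts.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        bad = counts.libraries[int(zero[0])].library_id
        raise ValueError(f"library {bad!r} has zero total count")
    lens = np.array([lengths[i] for i in counts.unigene_ids], dtype=float)
    fpkm = counts.values * 1e9 / (lens[:, None] * totals[None, :])
    return ExpressionMatrix(
        unigene_ids=list(counts.unigene_ids),
        libraries=list(counts.libraries),
        values=fpkm,
        value_kind="fpkm",
    )


def presence_calls(
    fpkm: ExpressionMatrix,
    config: RunConfig,
    groups: Sequence[str] = ("CD", "HC", "HA", "HI"),
) -> dict[str, PresenceSet]:
    """Presence set per tissue group under the FPKM threshold rule."""
    if fpkm.value_kind != "fpkm":
        raise ValueError("presence_calls expects an FPKM matrix")
    out: dict[str, PresenceSet] = {}
    ids = np.asarray(fpkm.unigene_ids)
    for group in groups:
        cols = fpkm.group_columns(group)
        if not cols:
            raise ValueError(f"group {group!r} has zero libraries")
        n_hit = (fpkm.values[:, cols] >= config.fpkm_threshold).sum(axis=1)
        present = ids[n_hit >= config.min_replicates_present]
        out[group] = PresenceSet(
            group=group,
            present_ids=frozenset(present.tolist()),
            rule=(config.fpkm_threshold, config.min_replicates_present),
        )
    return out


def mean_group_fpkm(fpkm: ExpressionMatrix, group: str) -> pd.Series:
    """Per-unigene mean FPKM over a group's replicates."""
    vals = fpkm.group_values(group).mean(axis=1)
    return pd.Series(vals, index=fpkm.unigene_ids, name=group)


def write_presence(presence: Mapping[str, PresenceSet], path: str | Path) -> None:
    rows = [
        (group, uid)
        for group in sorted(presence)
        for uid in sorted(presence[group].present_ids)
    ]
    pd.DataFrame(rows, columns=["group", "unigene_id"]).to_csv(path, sep="\t", index=False)


def read_presence(path: str | Path, config: RunConfig) -> dict[str, PresenceSet]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for group, sub in df.groupby("group"):
        out[str(group)] = PresenceSet(
            group=str(group),
            present_ids=frozenset(sub["unigene_id"].astype(str)),
            rule=(config.fpkm_threshold, config.min_replicates_present),
        )
    return out
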