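"""Downstream characterization of mobile transcripts.

Abundance contrasts (rank-sum), source-destination correlation,
upper-tail hypergeometric pathway enrichment with Benjamini-Hochberg
FDR control, and orthogroup gene-loss set analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, RunConfig
from .expression import mean_group_fpkm
from .mobility import MobilityCall


# ---------------------------------------------------------------------------
# Abundance contrasts

@dataclass
class AbundanceContrast:
    """Mobile vs non-mobile source-tissue abundance comparison."""

    group: str
    n_mobile: int
    n_non_mobile: int
    quantiles_mobile: Optional[dict[str, float]]
    quantiles_non_mobile: Optional[dict[str, float]]
    statistic: Optional[float]
    p_value: Optional[float]


def _log_quantiles(values: np.ndarray, pseudocount: float) -> dict[str, float]:
    logs = np.log10(values + pseudocount)
    qs = np.quantile(logs, [0.25, 0.5, 0.75])
    return {"q25": float(qs[0]), "median": float(qs[1]), "q75": float(qs[2])}


def abundance_contrast(
    fpkm: ExpressionMatrix,
    calls: Sequence[MobilityCall],
    group: str,
    config: RunConfig,
) -> AbundanceContrast:
    """Rank-sum contrast of mean source-group FPKM between mobile and
    non-mobile unigenes.  The mobile class for a source group is the
    direction originating there (CD -> CD_to_HC, HC -> HC_to_CD).

    Two-sided Mann-Whitney; the statistic is reported missing when a
    class has fewer than 2 members.
    """
    direction = {"CD": "CD_to_HC", "HC": "HC_to_CD"}.get(group)
    if direction is None:
        raise ValueError("abundance contrasts are defined for source groups CD and HC")
    means = mean_group_fpkm(fpkm, group)
    mobile_ids = [c.unigene_id for c in calls if c.direction == direction]
    non_ids = [c.unigene_id for c in calls if c.direction == "non_mobile"]
    # restrict both classes to unigenes expressed in the source tissue,
    # otherwise the non-mobile class is padded with the other species'
    # (necessarily absent) transcripts
    mob = means.loc[[i for i in mobile_ids if i in means.index]].to_numpy()
    non = means.loc[[i for i in non_ids if i in means.index]].to_numpy()
    mob = mob[mob > 0]
    non = non[non > 0]
    if len(mob) < 2 or len(non) < 2:
        return AbundanceContrast(group, len(mob), len(non),
                                 None, None, None, None)
    method = "exact" if min(len(mob), len(non)) < 10 else "asymptotic"
    res = sps.mannwhitneyu(mob, non, alternative="two-sided", method=method)
    return AbundanceContrast(
        group=group,
        n_mobile=len(mob),
        n_non_mobile=len(non),
        quantiles_mobile=_log_quantiles(mob, config.log_pseudocount),
        quantiles_non_mobile=_log_quantiles(non, config.log_pseudocount),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def source_dest_correlation(
    fpkm: ExpressionMatrix,
    calls: Sequence[MobilityCall],
    direction: str,
    config: RunConfig,
    dest_group: Optional[str] = None,
) -> tuple[float, float, int]:
    """Spearman rho and log-scale Pearson r between per-unigene mean
    source-group and destination-group FPKM for one mobile direction.

    *dest_group* defaults to the direction's destination tissue; pass
    "HI" for source-vs-haustorium comparisons.
    """
    src_group, default_dest = {
        "CD_to_HC": ("CD", "HC"),
        "HC_to_CD": ("HC", "CD"),
    }[direction]
    dest_group = dest_group or default_dest
    ids = [c.unigene_id for c in calls if c.direction == direction]
    if len(ids) < 3:
        raise ValueError(f"need >= 3 mobile unigenes for {direction}, got {len(ids)}")
    src = mean_group_fpkm(fpkm, src_group).loc[ids].to_numpy()
    dst = mean_group_fpkm(fpkm, dest_group).loc[ids].to_numpy()
    rho = float(sps.spearmanr(src, dst).statistic)
    pc = config.log_pseudocount
    r = float(sps.pearsonr(np.log10(src + pc), np.log10(dst + pc)).statistic)
    return rho, r, len(ids)


# ---------------------------------------------------------------------------
# Pathway enrichment

@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k_in_set: int
    K_in_background: int
    n_set: int
    N_background: int
    p_value: float
    p_adjusted: float
    enriched: bool


def hypergeometric_enrichment(
    set_ids: set[str],
    background_ids: set[str],
    annotation: Mapping[str, set[str]],
    config: RunConfig,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test per term with BH adjustment.

    p = P[X >= k] for X ~ Hypergeom(N background genes, K annotated,
    n drawn); terms are enriched when the BH-adjusted p is below
    ``fdr_alpha``.  Annotation members outside the background are
    ignored (the background defines the tested universe).
    """
    if not set_ids <= background_ids:
        extra = sorted(set_ids - background_ids)[:3]
        raise ValueError(f"set_ids not a subset of background_ids (e.g. {extra})")
    N = len(background_ids)
    n = len(set_ids)
    terms = sorted(annotation)
    raw: list[float] = []
    meta: list[tuple[str, int, int]] = []
    for term in terms:
        members = annotation[term] & background_ids
        K = len(members)
        k = len(members & set_ids)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        raw.append(min(p, 1.0))
        meta.append((term, k, K))
    if not raw:
        return []
    _, p_adj, _, _ = multipletests(raw, method="fdr_bh")
    out = []
    for (term, k, K), p, q in zip(meta, raw, p_adj):
        out.append(EnrichmentResult(
            term_id=term, k_in_set=k, K_in_background=K,
            n_set=n, N_background=N,
            p_value=p, p_adjusted=float(q),
            enriched=bool(q < config.fdr_alpha),
        ))
    out.sort(key=lambda r: (r.p_adjusted, r.p_value, r.term_id))
    return out


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# Orthogroup gene-loss analysis

def orthogroup_loss(
    matrix: pd.DataFrame,
    focal: str,
    asterid_refs: Sequence[str],
    comparators: Sequence[str],
    min_asterid_present: int = 3,
) -> dict:
    """Gene-loss set analysis over an orthogroup x species boolean matrix.

    Conserved orthogroups are those present in >= *min_asterid_present*
    of the reference asterid species; the missing set is conserved \\
    focal.  For each comparator (and their union) the fraction of the
    focal species' missing orthogroups that are also absent there is
    rendered as a 2-decimal percent.
    """
    for sp in [focal, *asterid_refs, *comparators]:
        if sp not in matrix.columns:
            raise ValueError(f"species {sp!r} absent from orthogroup matrix")
    presence = matrix.astype(bool)
    conserved = presence.index[presence[list(asterid_refs)].sum(axis=1) >= min_asterid_present]
    missing = [og for og in conserved if not presence.at[og, focal]]
    report = {
        "focal": focal,
        "n_conserved": len(conserved),
        "n_missing_in_focal": len(missing),
        "shared_missing": {},
    }
    union_shared = set()
    for comp in comparators:
        shared = [og for og in missing if not presence.at[og, comp]]
        union_shared.update(shared)
        report["shared_missing"][comp] = {
            "n_shared": len(shared),
            "pct": round(100.0 * len(shared) / len(missing), 2) if missing else None,
        }
    report["shared_missing_union"] = {
        "n_shared": len(union_shared),
        "pct": round(100.0 * len(union_shared) / len(missing), 2) if missing else None,
    }
    return report


def shared_missing_pct(n_shared: int, n_missing: int) -> float:
    """Two-decimal percent of focal-species missing orthogroups also
    absent from a comparator set."""
    if n_missing <= 0:
        raise ValueError("n_missing must be positive")
    return round(100.0 * n_shared / n_missing, 2)
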