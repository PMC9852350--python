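"""Paired host/parasite transcriptome generator with known ground truth.

The generator emulates the study system that the pipeline targets: a
host plant and a root holoparasite from two diverged plant families,
sampled in four tissue groups --

* ``CD``: parasite stem (3 replicates),
* ``HC``: parasitized host root (3 replicates),
* ``HA``: parasite-free host root (3 replicates),
* ``HI``: the haustorial interface (1 replicate).

Each species carries a set of transcripts; a configurable fraction are
conserved orthologs (present in both species at within-family sequence
identity), and disjoint fractions of the species-exclusive transcripts
are *mobile*: a parasite transcript trafficked into the parasitized host
root (CD->HC) appears in HC libraries at ``transfer_dilution`` times its
source abundance, and vice versa for HC->CD.  Nearly all mobile
transcripts are also present at the haustorial interface (Bernoulli
with direction-specific probabilities).  Every species transcript has a
diverged cousin in its own family's reference collection and a distant
homolog in the other family's collection, so family-of-origin
assignment by sequence similarity is exercisable end to end.

Divergence is substitution-only (no indels), which keeps the k-mer
containment / identity relation analytic.  Replicate counts are drawn
negative-binomially around length- and depth-scaled expectations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    SampleDesign,
    UnigeneRecord,
    default_design,
    write_expression_table,
    write_fasta,
)
from . import orf_screen

#: family reference labels (parasite family first)
PARASITE_FAMILY = "orobanchaceae_like"
HOST_FAMILY = "chenopodiaceae_like"

_BASES = "ACGT"
_CODE = {c: i for i, c in enumerate(_BASES)}
# codon codes (A=0, C=1, G=2, T=3)
_ATG = np.array([0, 3, 2], dtype=np.uint8)
_TAA = np.array([3, 0, 0], dtype=np.uint8)
_STOP_CODES = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA TAG TGA


_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _c, _i in _CODE.items():
    _ENCODE[ord(_c)] = _i


def _decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


def _encode(seq: str) -> np.ndarray:
    codes = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes == 255).any():
        bad = int(np.argmax(codes == 255))
        raise ValueError(f"non-ACGT character {seq[bad]!r} at position {bad}")
    return codes


def _mutate_codes(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site independently with probability *rate* to a
    uniformly chosen different base."""
    out = codes.copy()
    mask = rng.random(codes.size) < rate
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n)) % 4
    return out


def mutate_sequence(seq: str, rate: float, seed: int) -> str:
    """Per-site substitution at *rate*; length preserved, deterministic."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return _decode(_mutate_codes(_encode(seq), rate, rng))


# ---------------------------------------------------------------------------
# ORF planting / clearing on code arrays

def _plant_orf(codes: np.ndarray, orf_nt: int, rng: np.random.Generator) -> int:
    """Overwrite a frame-aligned window with ATG + non-stop codons + stop.

    Returns the 0-based start of the planted window (frame +1 relative
    to the window start, codon-aligned to the sequence start).
    """
    n_slots = (codes.size - orf_nt) // 3 + 1
    start = 3 * int(rng.integers(0, n_slots))
    codes[start:start + 3] = _ATG
    n_inner = orf_nt // 3 - 2
    inner = rng.integers(0, 4, size=(n_inner, 3)).astype(np.uint8)
    for i in range(n_inner):
        while tuple(inner[i]) in _STOP_CODES:
            inner[i] = rng.integers(0, 4, size=3)
    codes[start + 3:start + orf_nt - 3] = inner.ravel()
    codes[start + orf_nt - 3:start + orf_nt] = _TAA
    return start


def _repair_orf(codes: np.ndarray, start: int, orf_nt: int) -> None:
    """Restore the planted ORF after divergence mutations: re-set the
    start codon, convert interior in-frame stops to non-stops (third
    base -> C), re-set the terminal stop."""
    codes[start:start + 3] = _ATG
    for pos in range(start + 3, start + orf_nt - 3, 3):
        if tuple(codes[pos:pos + 3]) in _STOP_CODES:
            codes[pos + 2] = 1  # TAA->TAC, TAG->TAC, TGA->TGC
    codes[start + orf_nt - 3:start + orf_nt] = _TAA


def _break_orfs(codes: np.ndarray, min_orf_nt: int, rng: np.random.Generator,
                gene_id: str = "tmp") -> None:
    """Destroy every six-frame ATG..stop ORF >= *min_orf_nt* by stomping
    a stop codon into a random interior codon, so that non-coding
    synthetic transcripts are truly ORF-free for the screen.

    The position is randomized because overlapping forward/reverse ORFs
    can otherwise undo each other's edits indefinitely.
    """
    for _ in range(200):
        rec = UnigeneRecord(gene_id, _decode(codes))
        hits = orf_screen.find_orfs(rec, min_orf_nt)
        if not hits:
            return
        for h in hits:
            n_codons = h.length_nt // 3
            mid = int(rng.integers(1, n_codons - 1))  # interior: not ATG, not stop
            if h.frame > 0:
                pos = h.start + 3 * mid
                codes[pos:pos + 3] = _TAA
            else:
                # codon `mid` of the reverse-strand ORF occupies forward
                # positions [end - 3*(mid+1), end - 3*mid)
                end = h.start + h.length_nt
                pos = end - 3 * (mid + 1)
                codes[pos:pos + 3] = np.array([3, 3, 0], dtype=np.uint8)  # revcomp(TAA)
    raise RuntimeError(f"could not clear ORFs from synthetic transcript {gene_id}")


# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic dual transcriptome.

    Defaults mirror the study conditions: 3/3/3/1 replicates over
    CD/HC/HA/HI, a parasite->host transfer bias, haustorium presence
    probabilities 0.99 (CD->HC) / 0.81 (HC->CD) for mobile transcripts,
    and an FPKM-detectable dilution of transferred transcripts.
    """

    n_host_genes: int = 2000
    n_parasite_genes: int = 2000
    frac_conserved_orthologs: float = 0.25
    within_family_divergence: float = 0.05
    between_family_divergence: float = 0.40
    frac_mobile_parasite_to_host: float = 0.10
    frac_mobile_host_to_parasite: float = 0.03
    transfer_dilution: float = 0.10
    p_haustorium_given_mobile_cd: float = 0.99
    p_haustorium_given_mobile_ha: float = 0.81
    mean_len_nt: int = 1000
    nb_dispersion: float = 10.0
    library_size: int = 3_000_000
    frac_coding: float = 0.8
    planted_orf_nt: int = 300
    abundance_meanlog: float = 1.5
    abundance_sdlog: float = 1.0
    mobile_abundance_factor: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in (
            "frac_conserved_orthologs", "frac_mobile_parasite_to_host",
            "frac_mobile_host_to_parasite", "frac_coding",
            "p_haustorium_given_mobile_cd", "p_haustorium_given_mobile_ha",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 <= self.within_family_divergence <= 0.3):
            raise ValueError("within_family_divergence must be in [0, 0.3]")
        if not (0.0 <= self.between_family_divergence <= 0.6):
            raise ValueError("between_family_divergence must be in [0, 0.6]")
        if not (0.0 < self.transfer_dilution <= 1.0):
            raise ValueError("transfer_dilution must be in (0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.planted_orf_nt < 9 or self.planted_orf_nt % 3:
            raise ValueError("planted_orf_nt must be a multiple of 3, >= 9")
        n_cons = self.n_conserved_pairs
        if self.n_mobile_parasite > self.n_parasite_genes - n_cons:
            raise ValueError(
                "infeasible config: mobile parasite fraction exceeds the "
                "non-conserved parasite gene pool"
            )
        if self.n_mobile_host > self.n_host_genes - n_cons:
            raise ValueError(
                "infeasible config: mobile host fraction exceeds the "
                "non-conserved host gene pool"
            )

    # class sizes (rounding: nearest integer, ties to even via np.rint)
    @property
    def n_conserved_pairs(self) -> int:
        return int(np.rint(self.frac_conserved_orthologs
                           * min(self.n_host_genes, self.n_parasite_genes)))

    @property
    def n_mobile_parasite(self) -> int:
        return int(np.rint(self.frac_mobile_parasite_to_host * self.n_parasite_genes))

    @property
    def n_mobile_host(self) -> int:
        return int(np.rint(self.frac_mobile_host_to_parasite * self.n_host_genes))


TRUTH_COLUMNS = (
    "species_of_origin", "mobility", "conserved_ortholog", "in_haustorium",
    "coding", "length", "true_source_abundance", "true_dest_abundance",
)


def _draw_lengths(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    lo = cfg.planted_orf_nt + 90
    lengths = rng.lognormal(math.log(cfg.mean_len_nt) - 0.045, 0.3, size=n)
    return np.clip(np.rint(lengths), lo, 4 * cfg.mean_len_nt).astype(int)


def simulate_transcriptomes(
    config: SimulationConfig,
) -> tuple[list[UnigeneRecord], list[UnigeneRecord], dict[str, list[UnigeneRecord]], pd.DataFrame]:
    """Generate host and parasite transcript sets, two family reference
    collections and a complete truth table.

    Conserved-ortholog pairs descend from a shared ancestor with each
    branch (species copies and family-reference cousins) mutated at half
    the within-family divergence, so every pairwise distance within the
    family neighbourhood is ~``within_family_divergence``.  Exclusive
    genes get an own-family cousin at the within-family rate and a
    distant homolog in the other family at the between-family rate.
    """
    rng = np.random.default_rng([config.seed, 0])
    n_cons = config.n_conserved_pairs
    nh, np_ = config.n_host_genes, config.n_parasite_genes
    half = config.within_family_divergence / 2.0

    host_ids = [f"h{i:05d}" for i in range(nh)]
    para_ids = [f"p{i:05d}" for i in range(np_)]

    # coding flags: exact counts per species
    def coding_flags(n: int) -> np.ndarray:
        k = int(np.rint(config.frac_coding * n))
        flags = np.zeros(n, dtype=bool)
        flags[rng.permutation(n)[:k]] = True
        return flags

    host_coding = coding_flags(nh)
    para_coding = coding_flags(np_)

    # mobile subsets: drawn from the species-exclusive pools
    host_excl = np.arange(n_cons, nh)
    para_excl = np.arange(n_cons, np_)
    mobile_host = set(rng.choice(host_excl, size=config.n_mobile_host, replace=False).tolist()) \
        if config.n_mobile_host else set()
    mobile_para = set(rng.choice(para_excl, size=config.n_mobile_parasite, replace=False).tolist()) \
        if config.n_mobile_parasite else set()

    host_len = _draw_lengths(rng, nh, config)
    para_len = _draw_lengths(rng, np_, config)
    # a conserved pair shares the ancestor, hence the length
    para_len[:n_cons] = host_len[:n_cons]

    host_records: list[UnigeneRecord] = []
    para_records: list[UnigeneRecord] = []
    refs: dict[str, list[UnigeneRecord]] = {HOST_FAMILY: [], PARASITE_FAMILY: []}

    def finalize(codes: np.ndarray, coding: bool, window: tuple[int, int] | None,
                 gene_id: str) -> np.ndarray:
        if coding and window is not None:
            _repair_orf(codes, window[0], window[1])
        elif not coding:
            _break_orfs(codes, config.planted_orf_nt, rng, gene_id)
        return codes

    # conserved ortholog pairs
    for i in range(n_cons):
        L = int(host_len[i])
        anc = rng.integers(0, 4, size=L).astype(np.uint8)
        window = None
        if host_coding[i] or para_coding[i]:
            window = (_plant_orf(anc, config.planted_orf_nt, rng), config.planted_orf_nt)
        h = finalize(_mutate_codes(anc, half, rng), bool(host_coding[i]), window, host_ids[i])
        p = finalize(_mutate_codes(anc, half, rng), bool(para_coding[i]), window, para_ids[i])
        host_records.append(UnigeneRecord(host_ids[i], _decode(h)))
        para_records.append(UnigeneRecord(para_ids[i], _decode(p)))
        refs[HOST_FAMILY].append(
            UnigeneRecord(f"che_c{i:05d}", _decode(_mutate_codes(anc, half, rng))))
        refs[PARASITE_FAMILY].append(
            UnigeneRecord(f"oro_c{i:05d}", _decode(_mutate_codes(anc, half, rng))))

    # species-exclusive genes
    for i in range(n_cons, nh):
        g = rng.integers(0, 4, size=int(host_len[i])).astype(np.uint8)
        window = (_plant_orf(g, config.planted_orf_nt, rng), config.planted_orf_nt) \
            if host_coding[i] else None
        g = finalize(g, bool(host_coding[i]), window, host_ids[i])
        host_records.append(UnigeneRecord(host_ids[i], _decode(g)))
        refs[HOST_FAMILY].append(UnigeneRecord(
            f"che_c{i:05d}", _decode(_mutate_codes(g, config.within_family_divergence, rng))))
        refs[PARASITE_FAMILY].append(UnigeneRecord(
            f"oro_x{i:05d}", _decode(_mutate_codes(g, config.between_family_divergence, rng))))
    for i in range(n_cons, np_):
        g = rng.integers(0, 4, size=int(para_len[i])).astype(np.uint8)
        window = (_plant_orf(g, config.planted_orf_nt, rng), config.planted_orf_nt) \
            if para_coding[i] else None
        g = finalize(g, bool(para_coding[i]), window, para_ids[i])
        para_records.append(UnigeneRecord(para_ids[i], _decode(g)))
        refs[PARASITE_FAMILY].append(UnigeneRecord(
            f"oro_c{i:05d}", _decode(_mutate_codes(g, config.within_family_divergence, rng))))
        refs[HOST_FAMILY].append(UnigeneRecord(
            f"che_x{i:05d}", _decode(_mutate_codes(g, config.between_family_divergence, rng))))

    # ground truth
    rows = []
    for i, gid in enumerate(host_ids):
        mobility = "HC_to_CD" if i in mobile_host else "none"
        ab = float(rng.lognormal(config.abundance_meanlog, config.abundance_sdlog))
        if mobility != "none":
            ab *= config.mobile_abundance_factor
        if mobility == "none":
            in_hi, dest = True, 0.0
        else:
            in_hi = bool(rng.random() < config.p_haustorium_given_mobile_ha)
            dest = config.transfer_dilution * ab
        rows.append((gid, "host", mobility, i < n_cons, in_hi,
                     bool(host_coding[i]), int(host_len[i]), ab, dest))
    for i, gid in enumerate(para_ids):
        mobility = "CD_to_HC" if i in mobile_para else "none"
        ab = float(rng.lognormal(config.abundance_meanlog, config.abundance_sdlog))
        if mobility != "none":
            ab *= config.mobile_abundance_factor
        if mobility == "none":
            in_hi, dest = True, 0.0
        else:
            in_hi = bool(rng.random() < config.p_haustorium_given_mobile_cd)
            dest = config.transfer_dilution * ab
        rows.append((gid, "parasite", mobility, i < n_cons, in_hi,
                     bool(para_coding[i]), int(para_len[i]), ab, dest))

    truth = pd.DataFrame(rows, columns=("unigene_id",) + TRUTH_COLUMNS)
    truth = truth.set_index("unigene_id")
    return host_records, para_records, refs, truth


# ---------------------------------------------------------------------------
# Replicate counts

def _group_abundance(truth: pd.DataFrame, group: str) -> np.ndarray:
    """Expected relative abundance of every transcript in one tissue group."""
    origin = truth["species_of_origin"].to_numpy()
    mobility = truth["mobility"].to_numpy()
    src = truth["true_source_abundance"].to_numpy(float)
    dst = truth["true_dest_abundance"].to_numpy(float)
    in_hi = truth["in_haustorium"].to_numpy(bool)
    ab = np.zeros(len(truth))
    if group == "CD":
        ab[origin == "parasite"] = src[origin == "parasite"]
        m = mobility == "HC_to_CD"
        ab[m] = dst[m]
    elif group == "HC":
        ab[origin == "host"] = src[origin == "host"]
        m = mobility == "CD_to_HC"
        ab[m] = dst[m]
    elif group == "HA":
        ab[origin == "host"] = src[origin == "host"]
    elif group == "HI":
        # both organisms are present at the interface; mobile transcripts
        # appear per their in_haustorium flag
        ab[in_hi] = src[in_hi]
    else:
        raise ValueError(f"unknown group {group!r}")
    return ab


def expected_counts(
    truth: pd.DataFrame,
    design: Sequence[SampleDesign],
    config: SimulationConfig,
) -> ExpressionMatrix:
    """Expected (mean) counts per library: abundance x length x depth.

    The normalization constant is global (the total source-abundance x
    length mass over all transcripts), not per-library, so expected
    counts are directly comparable across tissue groups: a mobile
    transcript's expected destination count is exactly
    ``transfer_dilution`` times its expected source count.  Realized
    library totals therefore vary somewhat around ``library_size``.
    """
    groups = {d.group for d in design}
    if not {"CD", "HC", "HA", "HI"} <= groups:
        raise ValueError("design must cover the CD/HC/HA/HI groups")
    lengths = truth["length"].to_numpy(float)
    z = float((truth["true_source_abundance"].to_numpy(float) * lengths).sum())
    cols = []
    for d in design:
        ab = _group_abundance(truth, d.group)
        cols.append(ab * lengths / z * config.library_size)
    return ExpressionMatrix(
        unigene_ids=list(truth.index),
        libraries=list(design),
        values=np.column_stack(cols),
        value_kind="count",
    )


def simulate_counts(
    truth: pd.DataFrame,
    design: Sequence[SampleDesign],
    config: SimulationConfig,
) -> ExpressionMatrix:
    """Negative-binomial replicate counts around :func:`expected_counts`.

    ``nb_dispersion`` is the NB size parameter (variance = mu + mu^2 /
    dispersion); ``math.inf`` gives the Poisson limit.
    """
    mu = expected_counts(truth, design, config).values
    rng = np.random.default_rng([config.seed, 1])
    if math.isinf(config.nb_dispersion):
        counts = rng.poisson(mu).astype(float)
    else:
        r = config.nb_dispersion
        lam = np.zeros_like(mu)
        pos = mu > 0
        lam[pos] = rng.gamma(shape=r, scale=mu[pos] / r)
        counts = rng.poisson(lam).astype(float)
    return ExpressionMatrix(
        unigene_ids=list(truth.index),
        libraries=list(design),
        values=counts,
        value_kind="count",
    )


# ---------------------------------------------------------------------------
# Annotation surrogate (for the enrichment stage in synthetic runs)

def simulate_annotation(
    ids: Sequence[str],
    n_terms: int = 30,
    mean_term_size: int = 40,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Random term -> id-set annotation over *ids* (null structure)."""
    rng = np.random.default_rng([seed, 2])
    ids = list(ids)
    out: dict[str, set[str]] = {}
    for t in range(n_terms):
        size = int(np.clip(rng.poisson(mean_term_size), 5, len(ids)))
        members = rng.choice(len(ids), size=size, replace=False)
        out[f"term{t:03d}"] = {ids[j] for j in members}
    return out


# ---------------------------------------------------------------------------

def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t")


def read_truth(path: str | Path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("conserved_ortholog", "in_haustorium", "coding"):
        truth[col] = truth[col].astype(bool)
    return truth


def write_simulation(
    outdir: str | Path,
    host: Sequence[UnigeneRecord],
    parasite: Sequence[UnigeneRecord],
    refs: Mapping[str, Sequence[UnigeneRecord]],
    truth: pd.DataFrame,
    counts: ExpressionMatrix,
) -> dict[str, Path]:
    """Write all generator outputs in the formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "host_fasta": outdir / "host.fasta",
        "parasite_fasta": outdir / "parasite.fasta",
        "counts": outdir / "counts.tsv",
        "truth": outdir / "truth.tsv",
        "design": outdir / "design.tsv",
    }
    write_fasta(host, paths["host_fasta"])
    write_fasta(parasite, paths["parasite_fasta"])
    for label, records in refs.items():
        p = outdir / f"ref_{label}.fasta"
        write_fasta(records, p)
        paths[f"ref_{label}"] = p
    write_expression_table(counts, paths["counts"])
    write_truth(truth, paths["truth"])
    pd.DataFrame(
        [(d.library_id, d.group, d.replicate) for d in counts.libraries],
        columns=["library_id", "group", "replicate"],
    ).to_csv(paths["design"], sep="\t", index=False)
    return paths
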