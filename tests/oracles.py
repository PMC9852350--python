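"""Independent brute-force oracles used to validate the implementation.

Everything here is written as plainly as possible (nested loops,
explicit set enumeration) and never imports the code paths it checks.
"""

from __future__ import annotations

import numpy as np

_STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_orfs(seq: str, min_orf_nt: int) -> set[tuple[int, int, int]]:
    """All maximal ATG..stop ORFs in six frames, as (frame, fwd_start,
    length) triples.  Maximal: scanning backwards in-frame from the ATG
    hits a stop (or the sequence start) before any other ATG."""
    out: set[tuple[int, int, int]] = set()
    L = len(seq)

    def scan(s: str, strand: int) -> None:
        for i in range(len(s) - 2):
            if s[i:i + 3] != "ATG":
                continue
            stop = None
            j = i + 3
            while j + 3 <= len(s):
                c = s[j:j + 3]
                if "N" not in c and c in _STOPS:
                    stop = j
                    break
                j += 3
            if stop is None:
                continue
            length = stop + 3 - i
            if length < min_orf_nt:
                continue
            maximal = True
            k = i - 3
            while k >= 0:
                c = s[k:k + 3]
                if "N" in c:
                    k -= 3
                    continue
                if c in _STOPS:
                    break
                if c == "ATG":
                    maximal = False
                    break
                k -= 3
            if not maximal:
                continue
            frame = i % 3 + 1
            if strand > 0:
                out.add((frame, i, length))
            else:
                out.add((-frame, L - (i + length), length))

    scan(seq, +1)
    scan(revcomp(seq), -1)
    return out


def brute_force_venn(cd: set, hc: set, ha: set) -> dict[str, set]:
    """Enumerate every element's membership triple explicitly."""
    regions = {
        "CD_only": set(), "HC_only": set(), "HA_only": set(),
        "CD_HC": set(), "CD_HA": set(), "HC_HA": set(), "CD_HC_HA": set(),
    }
    for x in cd | hc | ha:
        key = (x in cd, x in hc, x in ha)
        name = {
            (True, False, False): "CD_only",
            (False, True, False): "HC_only",
            (False, False, True): "HA_only",
            (True, True, False): "CD_HC",
            (True, False, True): "CD_HA",
            (False, True, True): "HC_HA",
            (True, True, True): "CD_HC_HA",
        }[key]
        regions[name].add(x)
    return regions


def brute_force_presence(values: np.ndarray, cols: list[int],
                         threshold: float, min_reps: int) -> list[bool]:
    """Row-by-row re-evaluation of the presence rule."""
    out = []
    for row in values:
        hits = 0
        for c in cols:
            if row[c] >= threshold:
                hits += 1
        out.append(hits >= min_reps)
    return out


def brute_force_spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Rank correlation via explicit average ranks + Pearson formula."""

    def ranks(v: np.ndarray) -> np.ndarray:
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v), dtype=float)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for t in range(i, j + 1):
                r[order[t]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


def edlib_identity(a: str, b: str) -> float:
    """Global-alignment identity via edit distance (test-only oracle)."""
    import edlib

    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def brute_force_confusion(true_labels: dict[str, str],
                          called: dict[str, str]) -> dict:
    """Explicit per-direction TP/FP tallies."""
    out = {}
    for d in ("CD_to_HC", "HC_to_CD"):
        tp = sum(1 for i, c in called.items() if c == d and true_labels[i] == d)
        n_called = sum(1 for c in called.values() if c == d)
        n_true = sum(1 for t in true_labels.values() if t == d)
        out[d] = {
            "tp": tp,
            "fp": n_called - tp,
            "sensitivity": tp / n_true if n_true else None,
            "precision": tp / n_called if n_called else None,
        }
    return out
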