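"""Diversity and differentiation statistics with fifth-state gaps.

Implements the sequence statistics used to compare the ancient and extant
samples locus by locus: Nei's unbiased haplotype diversity Hd, mean
pairwise differences k, nucleotide diversity pi = k/L, and the Hudson
sequence-based differentiation statistics Ks, Kst = 1 - Ks/Kt and Fst,
with significance from label-permutation tests.

Alignment gaps are treated as fifth-state characters by default (a gap
differs from any base; two gaps at the same column match), matching the
convention used for length-variable chloroplast microsatellites. Sites
typed ``N`` in either sequence of a pair are always excluded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .haplotypes import collapse_haplotypes
from .seqio import SequenceRecord

GapMode = Literal["fifth_state", "pairwise_deletion"]


def _seq(x) -> str:
    return x.bases if isinstance(x, SequenceRecord) else str(x)


def pairwise_differences(seq_a, seq_b, gap_mode: GapMode = "fifth_state") -> int:
    """Number of differing sites between two equal-length aligned sequences.

    ``fifth_state``: a gap counts as its own character state, so gap-vs-base
    is a difference and gap-vs-gap is not. ``pairwise_deletion``: any site
    gapped in either sequence is excluded from the comparison.
    """
    a, b = _seq(seq_a), _seq(seq_b)
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} != {len(b)}")
    diffs = 0
    for x, y in zip(a, b):
        if x == "N" or y == "N":
            continue
        if gap_mode == "pairwise_deletion" and ("-" in (x, y)):
            continue
        if x != y:
            diffs += 1
    return diffs


def haplotype_diversity(counts: Sequence[int]) -> float:
    """Nei's unbiased haplotype diversity Hd = n(1 - sum p_i^2)/(n - 1)."""
    if any(c < 1 for c in counts):
        raise ValueError("haplotype counts must be >= 1")
    n = sum(counts)
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    sum_p2 = sum((c / n) ** 2 for c in counts)
    return n * (1.0 - sum_p2) / (n - 1)


def mean_pairwise_differences(
    records: Sequence, gap_mode: GapMode = "fifth_state"
) -> float:
    """Mean number of differences k over all unordered sequence pairs."""
    seqs = [_seq(r) for r in records]
    if len(seqs) < 2:
        raise ValueError("k requires at least two sequences")
    total = sum(
        pairwise_differences(a, b, gap_mode) for a, b in itertools.combinations(seqs, 2)
    )
    n = len(seqs)
    return total / (n * (n - 1) / 2)


def _compared_length(seqs: Sequence[str], gap_mode: GapMode) -> int:
    """Alignment length under the gap mode (pairwise_deletion: gap-free columns)."""
    length = len(seqs[0])
    if gap_mode == "fifth_state":
        return length
    return sum(
        1 for i in range(length) if all(s[i] != "-" for s in seqs)
    )


def nucleotide_diversity(records: Sequence, gap_mode: GapMode = "fifth_state") -> float:
    """Nucleotide diversity pi = k / L (L = compared sites under gap mode)."""
    seqs = [_seq(r) for r in records]
    k = mean_pairwise_differences(seqs, gap_mode)
    L = _compared_length(seqs, gap_mode)
    if L == 0:
        raise ValueError("no compared sites left after gap deletion")
    return k / L


def distance_matrix(records: Sequence, gap_mode: GapMode = "fifth_state") -> np.ndarray:
    """Symmetric matrix of pairwise fifth-state (or deletion-mode) differences."""
    seqs = [_seq(r) for r in records]
    n = len(seqs)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = pairwise_differences(seqs[i], seqs[j], gap_mode)
    return D


def _within_mean(D: np.ndarray, idx: np.ndarray) -> float:
    sub = D[np.ix_(idx, idx)]
    m = len(idx)
    if m < 2:
        raise ValueError("population must contain at least two sequences")
    return sub.sum() / (m * (m - 1))


def _between_mean(D: np.ndarray, idx1: np.ndarray, idx2: np.ndarray) -> float:
    return D[np.ix_(idx1, idx2)].mean()


def _ks_kst_from_matrix(D: np.ndarray, idx1: np.ndarray, idx2: np.ndarray):
    n1, n2 = len(idx1), len(idx2)
    k1 = _within_mean(D, idx1)
    k2 = _within_mean(D, idx2)
    w = n1 / (n1 + n2)
    ks = w * k1 + (1 - w) * k2
    pooled = np.concatenate([idx1, idx2])
    kt = _within_mean(D, pooled)
    kst = 0.0 if kt == 0 else 1.0 - ks / kt
    return ks, kt, kst


def _fst_from_matrix(D: np.ndarray, idx1: np.ndarray, idx2: np.ndarray) -> float:
    hw = 0.5 * (_within_mean(D, idx1) + _within_mean(D, idx2))
    hb = _between_mean(D, idx1, idx2)
    if hb == 0:
        return 0.0
    return 1.0 - hw / hb


def ks_kst(
    pop1: Sequence, pop2: Sequence, gap_mode: GapMode = "fifth_state"
) -> tuple[float, float, float]:
    """Hudson's (Ks, Kt, Kst).

    Ks is the within-population mean pairwise difference averaged with
    weight w = n1/(n1+n2); Kt is the mean pairwise difference of the pooled
    sample; Kst = 1 - Ks/Kt (0 when the pooled sample is monomorphic).
    """
    D = distance_matrix(list(pop1) + list(pop2), gap_mode)
    idx1 = np.arange(len(pop1))
    idx2 = np.arange(len(pop1), len(pop1) + len(pop2))
    return _ks_kst_from_matrix(D, idx1, idx2)


def fst_hudson(
    pop1: Sequence, pop2: Sequence, gap_mode: GapMode = "fifth_state", clip: bool = False
) -> float:
    """Hudson-style Fst = 1 - Hw/Hb.

    Hw is the *unweighted* mean of the two within-population mean pairwise
    differences and Hb the mean between-population pairwise difference —
    the same quantity as Kst up to the population-size weighting. Negative
    estimates are returned as computed unless ``clip`` is set.
    """
    D = distance_matrix(list(pop1) + list(pop2), gap_mode)
    idx1 = np.arange(len(pop1))
    idx2 = np.arange(len(pop1), len(pop1) + len(pop2))
    fst = _fst_from_matrix(D, idx1, idx2)
    return max(fst, 0.0) if clip else fst


def permutation_test(
    statistic: Literal["Kst", "Fst", "Ks"],
    pop1: Sequence,
    pop2: Sequence,
    n_perm: int = 1000,
    seed: int | None = None,
    gap_mode: GapMode = "fifth_state",
) -> float:
    """Label-permutation p-value for a differentiation statistic.

    Population labels are permuted uniformly at random preserving n1 and
    n2, and p = (1 + #extreme) / (1 + n_perm) (add-one estimator, never
    exactly zero). "Extreme" is directional toward differentiation:
    permuted Kst/Fst >= observed, permuted Ks <= observed (low
    within-population diversity relative to the pool indicates
    differentiation).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n1, n2 = len(pop1), len(pop2)
    if n1 + n2 < 4:
        raise ValueError("permutation test requires a combined sample of >= 4")
    D = distance_matrix(list(pop1) + list(pop2), gap_mode)

    def stat(idx1: np.ndarray, idx2: np.ndarray) -> float:
        if statistic == "Fst":
            return _fst_from_matrix(D, idx1, idx2)
        ks, _, kst = _ks_kst_from_matrix(D, idx1, idx2)
        return ks if statistic == "Ks" else kst

    all_idx = np.arange(n1 + n2)
    observed = stat(all_idx[:n1], all_idx[n1:])
    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(n_perm):
        perm = rng.permutation(all_idx)
        value = stat(perm[:n1], perm[n1:])
        if statistic == "Ks":
            extreme += value <= observed + 1e-12
        else:
            extreme += value >= observed - 1e-12
    return (1 + extreme) / (1 + n_perm)


def significance_stars(p: float | None) -> str:
    """Three-category significance label: ns (p>=0.05), * (<0.05), ** (<0.01)."""
    if p is None or not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def locus_summary_report(
    extant_by_locus: dict[str, Sequence[SequenceRecord]],
    ancient_by_locus: dict[str, Sequence[SequenceRecord]],
    loci: Iterable[str],
    gap_mode: GapMode = "fifth_state",
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-locus diversity and differentiation summary table.

    One row per locus and population with n, n_hap, Hd, pi and k, plus the
    locus-level Fst, Ks, Kst, permutation p and significance stars on the
    first row of each locus. Loci with fewer than two sequences in either
    population get diversity rows only, flagged in the ``note`` column.
    """
    rows = []
    for locus in loci:
        pops = {
            "Ancient": list(ancient_by_locus.get(locus, [])),
            "Extant": list(extant_by_locus.get(locus, [])),
        }
        diff: dict[str, float | str | None] = dict.fromkeys(
            ("Fst", "Ks", "Kst", "p_perm")
        )
        note = ""
        if all(len(v) >= 2 for v in pops.values()):
            ks, _, kst = ks_kst(pops["Ancient"], pops["Extant"], gap_mode)
            diff["Fst"] = fst_hudson(pops["Ancient"], pops["Extant"], gap_mode, clip=True)
            diff["Ks"], diff["Kst"] = ks, kst
            if n_perm > 0:
                diff["p_perm"] = permutation_test(
                    "Kst", pops["Ancient"], pops["Extant"], n_perm, seed, gap_mode
                )
        else:
            note = "insufficient sequences for differentiation"
        for j, (pop_name, recs) in enumerate(pops.items()):
            row = {"locus": locus, "population": pop_name, "n": len(recs), "note": note}
            if len(recs) >= 2:
                table = collapse_haplotypes(recs)
                row["n_hap"] = table.n_haplotypes
                row["Hd"] = haplotype_diversity(table.counts)
                row["k"] = mean_pairwise_differences(recs, gap_mode)
                row["pi"] = nucleotide_diversity(recs, gap_mode)
            else:
                row["note"] = (row["note"] + "; <2 sequences").lstrip("; ")
            if j == 0:
                row.update(diff)
                row["sig"] = (
                    significance_stars(diff["p_perm"])
                    if diff["p_perm"] is not None
                    else ""
                )
            rows.append(row)
    columns = [
        "locus", "population", "n", "n_hap", "Hd", "pi", "k",
        "Fst", "Ks", "Kst", "p_perm", "sig", "note",
    ]
    return pd.DataFrame(rows).reindex(columns=columns)
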