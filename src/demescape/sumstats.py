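"""Descriptive population genetics and the ABC summary-statistic vector.

Per-locality descriptives: haplotype count, haplotype diversity (Nei's
unbiased Hd), nucleotide diversity pi (mean per-site pairwise difference)
and Watterson's theta per site (both pi and theta_W estimate 2*N*mu for a
haploid locus).

For ABC inference, localities are pooled into G groups and a fixed, ordered
vector of statistics is computed: mean pairwise differences within each
group, overall mean and standard deviation of pairwise differences, Hudson's
FST for every unordered pair of groups and a global FST.  For the study
design of seven groups this yields 7 + 2 + 21 + 1 = 31 statistics.

FST uses the Hudson/Slatkin pairwise-difference form
``1 - H_w / H_b`` with ``H_w`` the average of the two within-group mean
differences and ``H_b`` the mean between-group difference (0 when
``H_b = 0``).  Inside FST the means are plug-in (frequency-weighted over
all ordered pairs, n^2 denominators) rather than sample-size corrected:
this makes the estimator exactly 0 for two identical groups and invariant
to duplicating every sequence, at the price of an O(1/n) downward bias that
the AMOVA cross-check tolerance covers.  The global variant weighs ``H_w``
by plug-in within-group pair counts.  The diversity entries (within-group
mean pairwise differences, pi) keep the conventional unbiased n(n-1)/2
denominators.  Sites carrying ambiguity codes are excluded pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateGroupError
from .sequences import Alignment

__all__ = [
    "HaplotypeDataset",
    "pairwise_difference_matrix",
    "diversity_stats",
    "fst_pair",
    "ss_vector",
    "ss_length",
    "ss_names",
]


@dataclass
class HaplotypeDataset:
    """An alignment whose group labels form a contiguous block 1..G."""

    alignment: Alignment

    def __post_init__(self) -> None:
        g = np.unique(self.alignment.groups)
        if g.size == 0 or not np.array_equal(g, np.arange(1, g.size + 1)):
            raise AlignmentError(
                f"group labels must be contiguous 1..G, got {g.tolist()}")

    @property
    def n_groups(self) -> int:
        return int(self.alignment.groups.max())


def _hap_collapse(codes: np.ndarray):
    """Unique haplotypes, per-sequence haplotype index and counts."""
    uniq, inverse, counts = np.unique(
        codes, axis=0, return_inverse=True, return_counts=True)
    return uniq, inverse.ravel(), counts


def _hap_distance_matrix(haps: np.ndarray) -> np.ndarray:
    """Hamming distances between haplotypes, ambiguity-excluded pairwise."""
    h = haps.shape[0]
    D = np.zeros((h, h), dtype=float)
    valid = haps < 4
    for i in range(h):
        diff = (haps[i] != haps) & valid[i] & valid
        D[i] = diff.sum(axis=1)
    return D


def pairwise_difference_matrix(aln: Alignment) -> np.ndarray:
    """Full n x n matrix of pairwise Hamming distances (complete sites only)."""
    if aln.codes.ndim != 2:
        raise AlignmentError("alignment codes must be 2-D")
    haps, inv, _ = _hap_collapse(aln.codes)
    D = _hap_distance_matrix(haps)
    return D[np.ix_(inv, inv)].astype(int)


def diversity_stats(codes: np.ndarray, n_sites: int | None = None):
    """(n_haplotypes, Hd, pi, theta_W) for one locality's sequences.

    ``Hd = n/(n-1) * (1 - sum p_i^2)`` (0 for a single sequence); ``pi`` is
    the mean pairwise difference per site; ``theta_W = S / (a1 * L)`` per
    site with ``a1 = sum_{i=1}^{n-1} 1/i``.
    """
    codes = np.asarray(codes, dtype=np.uint8)
    if codes.ndim != 2 or codes.shape[0] < 1:
        raise AlignmentError("need a 2-D matrix with at least one sequence")
    n, L = codes.shape
    if n_sites is None:
        n_sites = L
    haps, _inv, counts = _hap_collapse(codes)
    n_hap = haps.shape[0]
    if n == 1:
        return 1, 0.0, 0.0, 0.0
    p = counts / n
    hd = n / (n - 1) * (1.0 - float(p @ p))
    D = _hap_distance_matrix(haps)
    mean_pw = float(counts @ D @ counts) / 2.0 / (n * (n - 1) / 2.0)
    pi = mean_pw / n_sites
    valid = codes < 4
    seg = 0
    for j in range(L):
        col = codes[valid[:, j], j]
        if col.size and np.unique(col).size > 1:
            seg += 1
    a1 = float(np.sum(1.0 / np.arange(1, n)))
    theta_w = seg / (a1 * n_sites)
    return int(n_hap), hd, pi, theta_w


def _group_terms(D: np.ndarray, counts: np.ndarray):
    """(sum of pairwise differences, number of unordered pairs) for a group."""
    n = counts.sum()
    tot = float(counts @ D @ counts) / 2.0
    return tot, n * (n - 1) / 2.0


def fst_pair(codes_a: np.ndarray, codes_b: np.ndarray) -> float:
    """Hudson's FST between two groups of aligned sequences."""
    codes_a = np.asarray(codes_a, dtype=np.uint8)
    codes_b = np.asarray(codes_b, dtype=np.uint8)
    for name, c in (("a", codes_a), ("b", codes_b)):
        if c.shape[0] < 2:
            raise DegenerateGroupError(f"group {name} has fewer than 2 sequences")
    if codes_a.shape[1] != codes_b.shape[1]:
        raise AlignmentError("groups have different alignment lengths")
    both = np.vstack([codes_a, codes_b])
    haps, inv, _ = _hap_collapse(both)
    D = _hap_distance_matrix(haps)
    na, nb = codes_a.shape[0], codes_b.shape[0]
    ca = np.bincount(inv[:na], minlength=haps.shape[0]).astype(float)
    cb = np.bincount(inv[na:], minlength=haps.shape[0]).astype(float)
    hw = 0.5 * (float(ca @ D @ ca) / na**2 + float(cb @ D @ cb) / nb**2)
    hb = float(ca @ D @ cb) / (na * nb)
    if hb == 0.0:
        return 0.0
    return 1.0 - hw / hb


def ss_length(n_groups: int) -> int:
    """G within-group means + overall mean + overall SD + C(G,2) pairwise
    FST + 1 global FST."""
    return n_groups + 2 + n_groups * (n_groups - 1) // 2 + 1


def ss_names(n_groups: int) -> list[str]:
    names = [f"k_g{g}" for g in range(1, n_groups + 1)]
    names += ["k_all", "sd_all"]
    names += [f"fst_g{a}g{b}" for a in range(1, n_groups + 1)
              for b in range(a + 1, n_groups + 1)]
    names.append("fst_global")
    return names


def ss_vector(ds: HaplotypeDataset | Alignment) -> pd.Series:
    """The ordered ABC summary-statistic vector of a grouped dataset.

    Order: ``k_g1..k_gG`` (within-group mean pairwise differences),
    ``k_all`` and ``sd_all`` (mean and SD of pairwise differences over all
    sequences), pairwise FST in lexicographic group order, global FST.
    Invariant to the input order of sequences.
    """
    if isinstance(ds, Alignment):
        ds = HaplotypeDataset(ds)
    aln = ds.alignment
    G = ds.n_groups
    if G < 2:
        raise DegenerateGroupError("need at least 2 groups")
    haps, inv, _ = _hap_collapse(aln.codes)
    D = _hap_distance_matrix(haps)
    H = haps.shape[0]
    gcounts = np.zeros((G, H))
    for g in range(1, G + 1):
        gcounts[g - 1] = np.bincount(inv[aln.groups == g], minlength=H)
    sizes = gcounts.sum(axis=1)
    small = [g + 1 for g in range(G) if sizes[g] < 2]
    if small:
        raise DegenerateGroupError(f"groups with <2 sequences: {small}")

    values: list[float] = []
    tots = np.empty(G)
    pairs = np.empty(G)
    for g in range(G):
        tots[g], pairs[g] = _group_terms(D, gcounts[g])
        values.append(tots[g] / pairs[g])

    call = gcounts.sum(axis=0)
    tot_all, pairs_all = _group_terms(D, call)
    k_all = tot_all / pairs_all
    tot_sq_all = float(call @ (D * D) @ call) / 2.0
    var_all = tot_sq_all / pairs_all - k_all**2
    values += [k_all, float(np.sqrt(max(var_all, 0.0)))]

    # plug-in within-group heterozygosities for the FST entries
    hw_plug = np.array([float(gcounts[g] @ D @ gcounts[g]) / sizes[g]**2
                        for g in range(G)])
    hb_tot = 0.0
    hb_pairs = 0.0
    for a in range(G):
        for b in range(a + 1, G):
            cross = float(gcounts[a] @ D @ gcounts[b])
            npairs = sizes[a] * sizes[b]
            hw = 0.5 * (hw_plug[a] + hw_plug[b])
            hb = cross / npairs
            values.append(0.0 if hb == 0.0 else 1.0 - hw / hb)
            hb_tot += cross
            hb_pairs += npairs
    hw_global = float(hw_plug @ (sizes**2)) / float((sizes**2).sum())
    hb_global = hb_tot / hb_pairs
    values.append(0.0 if hb_global == 0.0 else 1.0 - hw_global / hb_global)
    return pd.Series(values, index=ss_names(G), dtype=float)
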