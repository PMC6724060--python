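"""Finite-sites sequence evolution and FASTA input/output.

Mutation follows a single-parameter uniform-substitution model (a
Jukes-Cantor-like finite-sites scheme): the root sequence is uniform random,
each branch receives Poisson(mu * L * branch_length) substitutions, each
substitution hits a uniform site and replaces the base with a uniform
*different* base.  mtDNA does not recombine, so one genealogy serves the
whole fragment (575 bp of COI by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import Genealogy
from .errors import AlignmentError, ParameterError

__all__ = ["Alignment", "mutate_sequences", "write_fasta", "read_fasta"]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {b: i for i, b in enumerate("ACGT")}
FASTA_WRAP = 70


@dataclass
class Alignment:
    """Aligned sequences with per-sample locality and group labels.

    ``codes`` is an (n, L) uint8 matrix over {0: A, 1: C, 2: G, 3: T};
    values >= 4 mark ambiguous/gap characters, which the statistics exclude
    pairwise.
    """

    codes: np.ndarray
    ids: list[str]
    localities: list[str]
    groups: np.ndarray
    _strings: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2:
            raise AlignmentError("codes must be a 2-D (samples x sites) matrix")
        n = self.codes.shape[0]
        if not (len(self.ids) == len(self.localities) == n and len(self.groups) == n):
            raise AlignmentError("label lengths do not match the sequence count")
        self.groups = np.asarray(self.groups, dtype=int)

    @property
    def n_sequences(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def sequence(self, i: int) -> str:
        row = self.codes[i]
        return "".join("ACGTN"[min(int(b), 4)] for b in row)


def mutate_sequences(gen: Genealogy, mu: float, n_sites: int = 575,
                     rng: np.random.Generator | int | None = None) -> Alignment:
    """Drop mutations on a genealogy and return the tip alignment.

    ``mu`` is the per-site per-generation substitution rate.
    """
    if mu < 0:
        raise ParameterError("mutation rate mu must be >= 0")
    if n_sites < 1:
        raise ParameterError("n_sites must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    bl = gen.branch_lengths()
    seqs = np.empty((gen.n_nodes, n_sites), dtype=np.uint8)
    root = gen.root
    seqs[root] = rng.integers(0, 4, n_sites, dtype=np.uint8)
    # parents always coalesce later than their children, so a descending-time
    # sweep visits every parent before its children
    order = np.argsort(-gen.node_time, kind="stable")
    n_mut = rng.poisson(mu * n_sites * bl)
    for node in order:
        if node == root:
            continue
        seq = seqs[gen.parent[node]].copy()
        k = int(n_mut[node])
        if k:
            sites = rng.integers(0, n_sites, k)
            shifts = rng.integers(1, 4, k).astype(np.uint8)
            for s, sh in zip(sites, shifts):  # sequential: later hits override
                seq[s] = (seq[s] + sh) % 4
        seqs[node] = seq

    groups = (gen.tip_group if gen.tip_group is not None
              else np.ones(gen.n_tips, dtype=int))
    locs = (gen.tip_locality if gen.tip_locality
            else [f"deme{gen.node_deme[i]}" for i in range(gen.n_tips)])
    ids = [f"s{i}" for i in range(gen.n_tips)]
    return Alignment(codes=seqs[: gen.n_tips], ids=ids,
                     localities=list(locs), groups=groups)


def write_fasta(aln: Alignment, path) -> None:
    """Write FASTA with ``>sampleID|locality|group`` headers, 70-col wrap."""
    with open(path, "w") as fh:
        for i in range(aln.n_sequences):
            fh.write(f">{aln.ids[i]}|{aln.localities[i]}|{int(aln.groups[i])}\n")
            s = aln.sequence(i)
            for j in range(0, len(s), FASTA_WRAP):
                fh.write(s[j:j + FASTA_WRAP] + "\n")


def read_fasta(path) -> Alignment:
    """Read a FASTA written by :func:`write_fasta` (or any plain FASTA).

    Headers of the form ``id|locality|group`` recover the labels; other
    headers get locality = id and group 1.  Non-ACGT characters are stored
    as the ambiguity code 4.
    """
    ids: list[str] = []
    locs: list[str] = []
    groups: list[int] = []
    seqs: list[str] = []
    cur: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if cur:
                    seqs.append("".join(cur))
                    cur = []
                parts = line[1:].split("|")
                ids.append(parts[0])
                locs.append(parts[1] if len(parts) > 1 else parts[0])
                groups.append(int(parts[2]) if len(parts) > 2 else 1)
            else:
                cur.append(line)
    if cur:
        seqs.append("".join(cur))
    if not seqs:
        raise AlignmentError(f"no sequences found in {path}")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise AlignmentError("sequences have unequal lengths")
    codes = np.full((len(seqs), L), 4, dtype=np.uint8)
    for i, s in enumerate(seqs):
        for j, ch in enumerate(s.upper()):
            codes[i, j] = _CODE.get(ch, 4)
    return Alignment(codes=codes, ids=ids, localities=locs,
                     groups=np.array(groups, dtype=int))
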