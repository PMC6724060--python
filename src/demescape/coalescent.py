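"""Structured coalescent conditioned on a recorded demography.

Gene genealogies are generated backward in time for samples taken at the
present of a :class:`~demescape.demography.DemographyTrace`.  Deme sizes are
interpreted directly as haploid gene-copy counts (mtDNA is maternally
inherited; a ``gene_copy_scale`` multiplier is exposed for other ploidies).
See :mod:`demescape._walk` for the walking rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _walk
from .demography import DemographyTrace, LDD
from .errors import SamplingError
from .landscape import DemeGrid, SamplingConfig

__all__ = ["Genealogy", "simulate_coalescent", "write_newick"]


@dataclass
class Genealogy:
    """A binary ultrametric coalescent tree over sampled gene copies.

    Nodes ``0..n_tips-1`` are the samples (time 0); internal nodes follow in
    coalescence order.  ``node_deme`` records the deme where each node was
    sampled or where the coalescence happened; ``tip_locality``/``tip_group``
    carry the sampling labels.
    """

    parent: np.ndarray      # int64, -1 for the root
    node_time: np.ndarray   # float64, generations before present
    node_deme: np.ndarray   # int32
    n_tips: int
    tip_locality: list[str] = field(default_factory=list)
    tip_group: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return int(np.nonzero(self.parent == -1)[0][0])

    def branch_lengths(self) -> np.ndarray:
        """Per-node branch length to the parent (0 for the root)."""
        bl = np.zeros(self.n_nodes)
        has = self.parent >= 0
        bl[has] = self.node_time[self.parent[has]] - self.node_time[has]
        return bl

    @property
    def tmrca(self) -> float:
        return float(self.node_time[self.root])

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                kids[p].append(i)
        return kids


def simulate_coalescent(
    trace: DemographyTrace,
    grid: DemeGrid,
    sampling: SamplingConfig | dict[int, int],
    n_ancestral: int | None = None,
    rng: np.random.Generator | int | None = None,
    gene_copy_scale: float = 1.0,
) -> Genealogy:
    """Simulate one genealogy for ``sampling`` conditioned on ``trace``.

    ``sampling`` maps demes to sample counts (a :class:`SamplingConfig` or a
    plain dict).  Every sampled deme must be occupied at the present of the
    trace.  ``rng`` may be a seed or a numpy Generator; the numba walker is
    seeded from it.
    """
    if isinstance(sampling, SamplingConfig):
        demes = np.repeat(sampling.deme_ids, sampling.sample_sizes)
        groups = np.repeat(sampling.groups, sampling.sample_sizes)
        locs = [name for name, s in zip(sampling.names, sampling.sample_sizes)
                for _ in range(int(s))]
    else:
        items = sorted(sampling.items())
        demes = np.concatenate([[d] * c for d, c in items]).astype(np.int64) \
            if items else np.empty(0, np.int64)
        groups = None
        locs = [f"deme{d}" for d, c in items for _ in range(c)]
    if demes.size == 0:
        raise SamplingError("empty sampling configuration")
    present = trace.sizes_at(trace.t_onset)
    for d in np.unique(demes):
        if present[d] < 1.0:
            raise SamplingError(f"sampled deme {int(d)} is empty at the present")
    if n_ancestral is None:
        n_ancestral = trace.params.n_ancestral
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    seed = int(rng.integers(0, 2**31 - 1))

    p = trace.params
    sizes = trace.sizes * gene_copy_scale
    parent, ntime, ndeme = _walk.backward_walk(
        demes.astype(np.int32),
        np.ascontiguousarray(sizes, dtype=np.float64),
        trace.gen_ptr,
        trace.imm_dst, trace.imm_src, trace.imm_cnt,
        np.int64(trace.t_onset), trace.stationary,
        float(p.carrying_capacity) * gene_copy_scale,
        float(p.migration_rate),
        float(p.ldd_fraction) if p.model == LDD else 0.0,
        float(p.ldd_gamma_shape), float(p.ldd_gamma_scale),
        float(p.ldd_min_demes), float(p.ldd_max_demes),
        grid.deme_rows, grid.deme_cols, grid.cell_to_deme,
        grid.nbr_indptr, grid.nbr_indices,
        np.int64(max(1, round(n_ancestral * gene_copy_scale))),
        np.int64(seed),
    )
    return Genealogy(
        parent=parent, node_time=ntime, node_deme=ndeme,
        n_tips=int(demes.size), tip_locality=locs,
        tip_group=None if groups is None else np.asarray(groups),
    )


def write_newick(gen: Genealogy, precision: int = 10) -> str:
    """Serialize a genealogy to Newick with branch lengths.

    Tips are labelled ``s<i>``; a one-tip genealogy degenerates to
    ``s0:0;``.
    """
    if gen.n_tips == 1:
        return "s0:0;"
    kids = gen.children()
    bl = gen.branch_lengths()

    out: list[str] = []
    # iterative post-order to avoid recursion limits on caterpillar trees
    stack: list[tuple[int, bool]] = [(gen.root, False)]
    frag: dict[int, str] = {}
    while stack:
        node, done = stack.pop()
        if not done:
            if kids[node]:
                stack.append((node, True))
                for c in kids[node]:
                    stack.append((c, False))
            else:
                frag[node] = f"s{node}:{bl[node]:.{precision}g}"
        else:
            inner = ",".join(frag.pop(c) for c in kids[node])
            if gen.parent[node] >= 0:
                frag[node] = f"({inner}):{bl[node]:.{precision}g}"
            else:
                out.append(f"({inner});")
    return out[0]
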