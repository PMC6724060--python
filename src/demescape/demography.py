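"""Forward-in-time range expansion on the deme lattice.

The metapopulation starts as a single ancestral deme and spreads over the
suitable lattice by logistic within-deme growth plus migration.  Two
migration models are implemented:

* **GDD** (gradual distance dispersal) — every generation a fraction ``m``
  of each deme's individuals emigrates and is split symmetrically among the
  suitable stepping-stone neighbours.
* **LDD** (long-distance dispersal) — identical, except that a fraction
  ``p_ldd`` of the emigrants instead draws a gamma-distributed jump distance
  (in deme units, truncated between ``ldd_min_demes`` and ``ldd_max_demes``)
  and a uniform direction; the landing cell is the nearest grid cell to the
  displaced point.

Densities are real-valued; stochastic rounding is applied only where integer
counts are required (emigrant emission), so migration conserves the total
population exactly.  Within a generation the order of events is growth first,
then migration.  The full per-generation demography (deme sizes and directed
migrant counts) is recorded in a :class:`DemographyTrace`, the conditioning
object for the backward coalescent.

For long simulations on connected grids the expansion saturates early: once
every deme is colonised (min density >= K/2) and the metapopulation holds at
least 97% of its total carrying capacity, the process fluctuates around a
statistical steady state.  ``simulate_forward(..., collapse_stationary=True)``
stops the explicit recording there and marks the remaining generations as a
stationary phase with sizes pinned at K; the backward walker handles that
phase with the matching stationary migration kernel.  The default is a fully
explicit trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ParameterError
from .landscape import DemeGrid

__all__ = [
    "SimParams",
    "DemographyTrace",
    "logistic_step",
    "stochastic_round",
    "migrate_gdd",
    "migrate_ldd",
    "simulate_forward",
]

GDD = "GDD"
LDD = "LDD"


@dataclass
class SimParams:
    """Parameters of one forward simulation.

    Priors used in the inference pipeline (see :mod:`demescape.abc`):
    ``t_onset`` U[15000, 20000] generations, ``n_ancestral`` U[100, 1000],
    ``growth_rate`` U[0.2, 0.9], ``migration_rate`` U[0.05, 0.30] and, for
    the LDD model only, ``ldd_fraction`` U[0.001, 0.05].
    """

    model: str
    t_onset: int
    n_ancestral: int
    growth_rate: float
    migration_rate: float
    carrying_capacity: int
    ldd_fraction: float = 0.0
    ldd_gamma_shape: float = 1.5
    ldd_gamma_scale: float = 10.0 / 1.5  # untruncated mean 10 demes
    ldd_min_demes: int = 2
    ldd_max_demes: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in (GDD, LDD):
            raise ParameterError(f"model must be {GDD!r} or {LDD!r}, got {self.model!r}")
        if self.model == GDD and self.ldd_fraction != 0.0:
            raise ParameterError("GDD model requires ldd_fraction == 0")
        if self.model == LDD and not 0.0 < self.ldd_fraction <= 1.0:
            raise ParameterError("LDD model requires 0 < ldd_fraction <= 1")
        if self.t_onset < 1:
            raise ParameterError("t_onset must be >= 1 generation")
        if self.n_ancestral < 1:
            raise ParameterError("n_ancestral must be >= 1")
        if self.carrying_capacity <= 0:
            raise ParameterError("carrying_capacity must be positive")
        if not 0.0 <= self.migration_rate <= 1.0:
            raise ParameterError("migration_rate must lie in [0, 1]")
        if self.ldd_min_demes < 2:
            raise ParameterError("ldd_min_demes must be >= 2 (an LDD jump spans >1 deme)")
        if self.ldd_max_demes < self.ldd_min_demes:
            raise ParameterError("ldd_max_demes must be >= ldd_min_demes")
        if self.ldd_gamma_shape <= 0 or self.ldd_gamma_scale <= 0:
            raise ParameterError("gamma kernel parameters must be positive")


@dataclass
class DemographyTrace:
    """Recorded per-generation demography of one forward simulation.

    Generation ``g`` runs forward from 0 (expansion onset) to ``t_onset``
    (the present).  ``sizes[g]`` are post-migration deme densities; the
    migrants that arrived during step ``g-1 -> g`` are stored, sorted by
    target deme, in the flat slice ``gen_ptr[g]:gen_ptr[g+1]`` of
    ``imm_dst``/``imm_src``/``imm_cnt``.

    When ``stationary`` is true the arrays only cover generations
    ``0..n_explicit`` and every later generation has all demes at
    ``carrying_capacity`` with the stationary migration kernel implied by
    ``params``.
    """

    t_onset: int
    origin_deme: int
    params: SimParams
    sizes: np.ndarray          # (n_explicit+1, n_demes) float64
    gen_ptr: np.ndarray        # (n_explicit+2,) int64
    imm_dst: np.ndarray        # int32, sorted by dst within each generation
    imm_src: np.ndarray        # int32
    imm_cnt: np.ndarray        # float64 (integer-valued counts)
    stationary: bool = False
    extinct: bool = False

    @property
    def n_explicit(self) -> int:
        return self.sizes.shape[0] - 1

    @property
    def n_demes(self) -> int:
        return self.sizes.shape[1]

    def sizes_at(self, g: int) -> np.ndarray:
        """Deme sizes at forward generation ``g`` (0 = onset)."""
        if not 0 <= g <= self.t_onset:
            raise KeyError(f"generation {g} outside [0, {self.t_onset}]")
        if g <= self.n_explicit:
            return self.sizes[g]
        # stationary plateau
        return np.full(self.n_demes, float(self.params.carrying_capacity))

    def immigrants_at(self, g: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(dst, src, count) arrays of migrants that arrived at generation g."""
        if not 1 <= g <= self.n_explicit:
            raise KeyError(f"no explicit migrant record for generation {g}")
        lo, hi = self.gen_ptr[g], self.gen_ptr[g + 1]
        return self.imm_dst[lo:hi], self.imm_src[lo:hi], self.imm_cnt[lo:hi]

    def save(self, path) -> None:
        """Write the trace as a compressed npz with a JSON params sidecar."""
        import dataclasses
        import json
        from pathlib import Path

        path = Path(path)
        np.savez_compressed(
            path, sizes=self.sizes, gen_ptr=self.gen_ptr,
            imm_dst=self.imm_dst, imm_src=self.imm_src, imm_cnt=self.imm_cnt,
            meta=np.array([self.t_onset, self.origin_deme,
                           int(self.stationary), int(self.extinct)]))
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(dataclasses.asdict(self.params), fh, indent=2)

    @classmethod
    def load(cls, path) -> "DemographyTrace":
        import json
        from pathlib import Path

        path = Path(path)
        with np.load(path) as z:
            meta = z["meta"]
            with open(path.with_suffix(path.suffix + ".json")) as fh:
                params = SimParams(**json.load(fh))
            return cls(t_onset=int(meta[0]), origin_deme=int(meta[1]),
                       params=params, sizes=z["sizes"], gen_ptr=z["gen_ptr"],
                       imm_dst=z["imm_dst"], imm_src=z["imm_src"],
                       imm_cnt=z["imm_cnt"], stationary=bool(meta[2]),
                       extinct=bool(meta[3]))


def logistic_step(n, r: float, k: float):
    """One generation of logistic growth: ``n + r*n*(1 - n/k)``, floored at 0.

    ``n`` may be a scalar or an array of deme densities.
    """
    if k <= 0:
        raise ParameterError("carrying capacity k must be positive")
    n = np.asarray(n, dtype=float)
    if (n < 0).any():
        raise ParameterError("density n must be non-negative")
    out = np.maximum(n + r * n * (1.0 - n / k), 0.0)
    return float(out) if out.ndim == 0 else out


def stochastic_round(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Round each entry up with probability equal to its fractional part."""
    x = np.asarray(x, dtype=float)
    lo = np.floor(x)
    return (lo + (rng.random(x.shape) < (x - lo))).astype(np.int64)


def _emigrant_counts(sizes, m, rng):
    sizes = np.asarray(sizes, dtype=float)
    emi = stochastic_round(m * sizes, rng)
    # a deme can only emit the whole individuals it holds
    return np.minimum(emi, np.floor(sizes).astype(np.int64))


def _split_to_neighbors(grid: DemeGrid, emi: np.ndarray, rng: np.random.Generator):
    """Multinomially split integer emigrant counts among suitable neighbours.

    Returns (dst, src, cnt) arrays and the per-deme number actually sent;
    demes without suitable neighbours retain their would-be migrants.
    """
    deg = np.diff(grid.nbr_indptr)
    sent = np.where(deg > 0, emi, 0)
    dst_parts, src_parts, cnt_parts = [], [], []
    for g in np.unique(deg[(sent > 0)]):
        idx = np.nonzero((deg == g) & (sent > 0))[0]
        counts = rng.multinomial(sent[idx], np.full(int(g), 1.0 / g))
        # neighbour ids for each of these demes, shape (len(idx), g)
        nb = grid.nbr_indices[
            grid.nbr_indptr[idx][:, None] + np.arange(int(g))[None, :]
        ]
        keep = counts > 0
        src_parts.append(np.repeat(idx, int(g)).reshape(-1, int(g))[keep])
        dst_parts.append(nb[keep])
        cnt_parts.append(counts[keep])
    if dst_parts:
        dst = np.concatenate(dst_parts).astype(np.int32)
        src = np.concatenate(src_parts).astype(np.int32)
        cnt = np.concatenate(cnt_parts).astype(np.float64)
    else:
        dst = np.empty(0, np.int32)
        src = np.empty(0, np.int32)
        cnt = np.empty(0, np.float64)
    return dst, src, cnt, sent


def migrate_gdd(sizes: np.ndarray, m: float, grid: DemeGrid,
                rng: np.random.Generator):
    """Stepping-stone migration step.

    Each deme emits a stochastically rounded ``m * n_i`` emigrants, split
    multinomially (equal probabilities) among its suitable neighbours.
    Returns ``(new_sizes, (dst, src, cnt))``; the total population is
    conserved exactly.
    """
    if not 0.0 <= m <= 1.0:
        raise ParameterError("migration rate m must lie in [0, 1]")
    sizes = np.asarray(sizes, dtype=float)
    emi = _emigrant_counts(sizes, m, rng)
    dst, src, cnt, sent = _split_to_neighbors(grid, emi, rng)
    new = sizes - sent
    np.add.at(new, dst, cnt)
    return new, (dst, src, cnt)


def _truncated_gamma(n: int, shape: float, scale: float, lo: float, hi: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw n gamma variates conditioned on [lo, hi] by rejection."""
    out = np.empty(n)
    todo = np.arange(n)
    for _ in range(1000):
        if todo.size == 0:
            break
        d = rng.gamma(shape, scale, todo.size)
        ok = (d >= lo) & (d <= hi)
        out[todo[ok]] = d[ok]
        todo = todo[~ok]
    if todo.size:  # pathological kernel: clamp the stragglers
        out[todo] = np.clip(rng.gamma(shape, scale, todo.size), lo, hi)
    return out


def migrate_ldd(sizes: np.ndarray, m: float, p_ldd: float, gamma_shape: float,
                gamma_scale: float, d_min: int, d_max: int, grid: DemeGrid,
                rng: np.random.Generator):
    """Migration step with a long-distance dispersal component.

    A Binomial(``emigrants``, ``p_ldd``) share of each deme's emigrants
    jumps: distance ~ Gamma(shape, scale) truncated to [d_min, d_max] deme
    units, direction uniform; the landing cell is the nearest grid cell.
    Landings outside the grid or on unsuitable cells are redrawn up to 10
    times, then cancelled (the migrant stays).  The remaining emigrants move
    as in :func:`migrate_gdd`.
    """
    if p_ldd == 0.0:
        return migrate_gdd(sizes, m, grid, rng)
    if not 0.0 < p_ldd <= 1.0:
        raise ParameterError("p_ldd must lie in (0, 1]")
    if d_min < 2 or d_max < d_min:
        raise ParameterError("need d_min >= 2 and d_max >= d_min")
    sizes = np.asarray(sizes, dtype=float)
    emi = _emigrant_counts(sizes, m, rng)
    n_ldd = rng.binomial(emi, p_ldd)
    dst, src, cnt, sent = _split_to_neighbors(grid, emi - n_ldd, rng)

    ldd_src = np.repeat(np.arange(grid.n_demes), n_ldd).astype(np.int64)
    landed_src, landed_dst = _ldd_landings(
        ldd_src, gamma_shape, gamma_scale, d_min, d_max, grid, rng)
    sent = sent + np.bincount(landed_src, minlength=grid.n_demes)
    new = sizes - sent
    np.add.at(new, dst, cnt)
    np.add.at(new, landed_dst, 1.0)
    if landed_src.size:
        key = landed_src.astype(np.int64) * grid.n_demes + landed_dst
        ukey, ucnt = np.unique(key, return_counts=True)
        dst = np.concatenate([dst, (ukey % grid.n_demes).astype(np.int32)])
        src = np.concatenate([src, (ukey // grid.n_demes).astype(np.int32)])
        cnt = np.concatenate([cnt, ucnt.astype(np.float64)])
    return new, (dst, src, cnt)


def _ldd_landings(ldd_src, gamma_shape, gamma_scale, d_min, d_max, grid, rng,
                  max_tries: int = 10):
    """Resolve LDD jump targets; events that never land are dropped (stay)."""
    src_ok = np.empty(0, np.int64)
    dst_ok = np.empty(0, np.int64)
    pending = ldd_src
    nr, nc = grid.suitable.shape
    for _ in range(max_tries):
        if pending.size == 0:
            break
        d = _truncated_gamma(pending.size, gamma_shape, gamma_scale,
                             float(d_min), float(d_max), rng)
        theta = rng.uniform(0.0, 2.0 * np.pi, pending.size)
        rr = np.rint(grid.deme_rows[pending] + d * np.sin(theta)).astype(np.int64)
        cc = np.rint(grid.deme_cols[pending] + d * np.cos(theta)).astype(np.int64)
        inside = (rr >= 0) & (rr < nr) & (cc >= 0) & (cc < nc)
        tgt = np.full(pending.size, -1, np.int64)
        tgt[inside] = grid.cell_to_deme[rr[inside], cc[inside]]
        ok = tgt >= 0
        src_ok = np.concatenate([src_ok, pending[ok]])
        dst_ok = np.concatenate([dst_ok, tgt[ok]])
        pending = pending[~ok]
    return src_ok, dst_ok


def simulate_forward(grid: DemeGrid, params: SimParams, origin_deme: int,
                     collapse_stationary: bool = False) -> DemographyTrace:
    """Run the range expansion and record its demographic trace.

    The simulation starts with ``n_ancestral`` individuals in
    ``origin_deme`` and iterates ``t_onset`` generations of logistic growth
    followed by migration under ``params.model``.  Fully reproducible from
    ``params.seed``.  With ``collapse_stationary`` the explicit recording
    stops once the expansion has saturated the grid (sizes are pinned to K
    thereafter); see the module docstring.
    """
    from . import _fstep

    if not 0 <= origin_deme < grid.n_demes:
        raise ConfigurationError(f"origin deme {origin_deme} is not a suitable deme")
    rng = np.random.default_rng(params.seed)
    nd = grid.n_demes
    k = float(params.carrying_capacity)
    m = params.migration_rate
    p_ldd = params.ldd_fraction if params.model == LDD else 0.0

    cap = int(grid.nbr_indices.size)
    if p_ldd > 0.0:
        cap += nd * (int(1.5 * m * k * p_ldd) + 2)
    buf_src = np.empty(cap, np.int32)
    buf_dst = np.empty(cap, np.int32)
    buf_cnt = np.empty(cap, np.float64)

    n = np.zeros(nd)
    n[origin_deme] = float(params.n_ancestral)
    sizes = [n.copy()]
    per_gen: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    stationary = False
    extinct = False
    target_total = 0.97 * nd * k

    for _g in range(1, params.t_onset + 1):
        gen_seed = np.int64(rng.integers(0, 2**31 - 1))
        while True:
            n_try = n.copy()
            n_rec = _fstep.forward_step(
                n_try, params.growth_rate, k, m, p_ldd,
                params.ldd_gamma_shape, params.ldd_gamma_scale,
                float(params.ldd_min_demes), float(params.ldd_max_demes),
                grid.nbr_indptr, grid.nbr_indices,
                grid.deme_rows, grid.deme_cols, grid.cell_to_deme,
                buf_src, buf_dst, buf_cnt, gen_seed)
            if n_rec >= 0:
                n = n_try
                break
            cap *= 2
            buf_src = np.empty(cap, np.int32)
            buf_dst = np.empty(cap, np.int32)
            buf_cnt = np.empty(cap, np.float64)
        dst = buf_dst[:n_rec].copy()
        src = buf_src[:n_rec].copy()
        cnt = buf_cnt[:n_rec].copy()
        order = np.argsort(dst, kind="stable")
        per_gen.append((dst[order], src[order], cnt[order]))
        sizes.append(n.copy())
        if n.sum() < 1.0:
            extinct = True
            break
        if (collapse_stationary and _g < params.t_onset
                and n.min() >= 0.5 * k and n.sum() >= target_total):
            stationary = True
            break

    gen_ptr = np.zeros(len(per_gen) + 2, dtype=np.int64)
    for i, (d, _s, _c) in enumerate(per_gen):
        gen_ptr[i + 2] = gen_ptr[i + 1] + d.size
    if per_gen:
        imm_dst = np.concatenate([d for d, _, _ in per_gen])
        imm_src = np.concatenate([s for _, s, _ in per_gen])
        imm_cnt = np.concatenate([c for _, _, c in per_gen])
    else:
        imm_dst = np.empty(0, np.int32)
        imm_src = np.empty(0, np.int32)
        imm_cnt = np.empty(0, np.float64)
    return DemographyTrace(
        t_onset=params.t_onset,
        origin_deme=origin_deme,
        params=params,
        sizes=np.asarray(sizes),
        gen_ptr=gen_ptr,
        imm_dst=imm_dst.astype(np.int32),
        imm_src=imm_src.astype(np.int32),
        imm_cnt=imm_cnt.astype(np.float64),
        stationary=stationary,
        extinct=extinct,
    )
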