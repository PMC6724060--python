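"""Synthetic landscapes, the study's sampling design, and self-consistent
observed datasets.

Everything the pipeline consumes can be generated here with no external
data: a raster emulating a chain of alpine "sky island" massifs, the
22-locality / 7-group / 327-individual sampling table of the study, and
observed-style FASTA datasets produced by the package's own simulator at
known ("true") parameters, so parameter-recovery tests have a ground truth.

All fixtures are reproducible byte-for-byte from their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .demography import GDD, LDD
from .errors import ConfigurationError
from .landscape import (DemeGrid, Landscape, SamplingConfig, make_deme_grid,
                        map_localities, write_ascii_grid, write_locality_csv)
from .sequences import Alignment, write_fasta

__all__ = [
    "FixtureSpec",
    "synth_landscape",
    "table1_fixture",
    "table1_landscape",
    "table1_bundle",
    "power_study_design",
    "synth_observed",
    "write_fixtures",
    "TABLE1_ROWS",
]

LOW_ELEV = 800.0
HIGH_ELEV = 1700.0
DEFAULT_THRESHOLD = 1400.0

#: (locality, acronym, sample size, group) — the study's sampling design:
#: 22 localities in 7 geographic groups, 327 individuals in total.
TABLE1_ROWS = [
    ("Cantu l'Osu", "COsu", 20, 1),
    ("Campiguenos", "Cam", 11, 2),
    ("Llambria", "Lla", 11, 2),
    ("Tiatordos", "Tia", 16, 2),
    ("Maciedome", "Mac", 18, 2),
    ("Pena Ten", "Ten", 15, 3),
    ("Pilenes", "Pil", 10, 3),
    ("Cantu Cabroneru", "CC", 15, 4),
    ("Traviesos", "Tra", 15, 5),
    ("Cotalba", "Cot", 15, 5),
    ("Vega Ario", "Va", 15, 5),
    ("Vega Huerta", "Vh", 16, 5),
    ("Vegarredonda", "VR", 17, 5),
    ("Tiros Navarros", "NV", 25, 6),
    ("Pena Castil", "PC", 16, 6),
    ("Liordes", "Lio", 6, 6),
    ("Urriellu", "U", 19, 6),
    ("Camburero", "Camb", 3, 6),
    ("Morra Lechugales", "MoHie", 19, 7),
    ("Andara", "A", 15, 7),
    ("Caseton Andara", "Ba", 15, 7),
    ("Rasa", "Ras", 15, 7),
]

ORIGIN_LOCALITY = "Urriellu"

# west-to-east order of the seven groups across the massif chain
# (western massifs carry groups 2-3, central 1/4/5, eastern 6-7)
_GROUP_ORDER = [2, 3, 1, 4, 5, 6, 7]


def synth_landscape(rows: int, cols: int, pattern: str = "ridge-corridor",
                    seed: int = 0, n_massifs: int = 7) -> Landscape:
    """Generate a synthetic elevation raster.

    Patterns: ``all`` (every cell alpine), ``ridge-corridor`` (``n_massifs``
    high-elevation blocks joined by a narrow 2-cell corridor, emulating sky
    islands linked by alpine corridors) and ``archipelago`` (the same blocks
    with no corridor, giving disconnected suitable components).
    """
    if rows < 2 or cols < 2:
        raise ConfigurationError("need rows, cols >= 2")
    rng = np.random.default_rng(seed)
    elev = np.full((rows, cols), LOW_ELEV)
    if pattern == "all":
        elev[:] = HIGH_ELEV
    elif pattern in ("ridge-corridor", "archipelago"):
        pitch = cols / n_massifs
        width = max(2, int(pitch) - 2)
        r0, r1 = rows // 4, rows - rows // 4
        for i in range(n_massifs):
            c0 = int(i * pitch) + 1
            elev[r0:r1, c0:c0 + width] = HIGH_ELEV
        if pattern == "ridge-corridor":
            mid = rows // 2
            elev[mid:mid + 2, 1:cols - 1] = HIGH_ELEV
    else:
        raise ConfigurationError(f"unknown pattern {pattern!r}")
    elev += rng.uniform(0.0, 100.0, elev.shape)  # relief, never crosses 1400
    return Landscape(n_rows=rows, n_cols=cols, elevation=elev)


def table1_landscape(rows: int = 40, cols: int = 40, seed: int = 7) -> Landscape:
    """The default ridge-corridor landscape carrying the 22-locality fixture."""
    return synth_landscape(rows, cols, "ridge-corridor", seed=seed)


def table1_fixture(rows: int = 40, cols: int = 40, seed: int = 7) -> pd.DataFrame:
    """The study's locality table with synthetic grid coordinates.

    22 localities, the study's acronyms / sample sizes / group labels (327
    individuals in 7 groups), placed on distinct suitable cells of the
    matching ridge-corridor landscape; the expansion origin is Urriellu.
    """
    land = table1_landscape(rows, cols, seed)
    grid = make_deme_grid(land, DEFAULT_THRESHOLD)
    pitch = cols / 7
    width = max(2, int(pitch) - 2)
    r0 = rows // 4
    recs = []
    counter: dict[int, int] = {}
    for name, acr, n, group in TABLE1_ROWS:
        i = counter.get(group, 0)
        counter[group] = i + 1
        massif = _GROUP_ORDER.index(group)
        c0 = int(massif * pitch) + 1
        row = r0 + 1 + 2 * i
        col = c0 + i % width
        if not grid.suitable[row, col]:  # pragma: no cover - layout guard
            raise ConfigurationError(f"fixture cell for {name} unsuitable")
        recs.append(dict(name=name, acronym=acr, sample_size=n, group=group,
                         row=row, col=col, is_origin=name == ORIGIN_LOCALITY))
    return pd.DataFrame.from_records(recs)


def table1_bundle(rows: int = 40, cols: int = 40, seed: int = 7):
    """(landscape, grid, locality table, sampling config) in one call."""
    land = table1_landscape(rows, cols, seed)
    grid = make_deme_grid(land, DEFAULT_THRESHOLD)
    table = table1_fixture(rows, cols, seed)
    return land, grid, table, map_localities(grid, table)


def power_study_design(rows: int = 30, cols: int = 30):
    """The scaled-down design of the model-choice power analysis.

    A fully suitable ``rows x cols`` grid with one sampled deme per group;
    each deme's sample size is its group's total in the study's table.  The
    group-6 deme (the Urriellu group) is the expansion origin.  Returns
    ``(grid, sampling_config)``.
    """
    land = synth_landscape(rows, cols, "all", seed=0)
    grid = make_deme_grid(land, DEFAULT_THRESHOLD)
    totals: dict[int, int] = {}
    for _name, _a, n, g in TABLE1_ROWS:
        totals[g] = totals.get(g, 0) + n
    rr = [rows // 4, rows - rows // 4, rows // 2]
    recs = []
    for i, g in enumerate(_GROUP_ORDER):
        row = rr[i % 3]
        col = 2 + int(i * (cols - 5) / 6)
        recs.append(dict(name=f"group{g}", acronym=f"G{g}",
                         sample_size=totals[g], group=g, row=row, col=col,
                         is_origin=g == 6))
    table = pd.DataFrame.from_records(recs)
    return grid, map_localities(grid, table)


@dataclass
class FixtureSpec:
    """Recipe for a self-consistent observed dataset."""

    rows: int = 40
    cols: int = 40
    pattern: str = "ridge-corridor"
    model: str = GDD
    true_params: dict = field(default_factory=lambda: dict(
        t_onset=17500, n_ancestral=550, growth_rate=0.55,
        migration_rate=0.17, carrying_capacity=300, mu=1.4e-6))
    n_sites: int = 575
    seed: int = 7

    def __post_init__(self) -> None:
        if self.model == LDD and "ldd_fraction" not in self.true_params:
            self.true_params = dict(self.true_params, ldd_fraction=0.02)


def synth_observed(spec: FixtureSpec | None = None):
    """Simulate an observed-style dataset at known parameters.

    Runs the full pipeline (forward expansion, coalescent, mutation) on the
    fixture landscape with the study's 22-locality sampling design and
    returns ``(alignment, locality_table, truth)`` where ``truth`` is the
    parameter record for recovery tests.
    """
    from .abc import simulate_dataset  # local import to avoid a cycle

    if spec is None:
        spec = FixtureSpec()
    if spec.pattern == "all":
        land = synth_landscape(spec.rows, spec.cols, "all", seed=spec.seed)
        grid = make_deme_grid(land, DEFAULT_THRESHOLD)
        table = table1_fixture(spec.rows, spec.cols, spec.seed)
        # project fixture coordinates onto the fully suitable grid
        sampling = map_localities(grid, table)
    else:
        land, grid, table, sampling = table1_bundle(spec.rows, spec.cols,
                                                    spec.seed)
    rng = np.random.default_rng(spec.seed)
    aln = simulate_dataset(spec.model, spec.true_params, grid, sampling, rng,
                           n_sites=spec.n_sites, collapse=True)
    truth = dict(spec.true_params, model=spec.model)
    return aln, table, truth


def write_fixtures(out_dir, pattern: str = "ridge-corridor", seed: int = 7):
    """Write grid.asc, localities.csv, observed.fasta and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = FixtureSpec(pattern=pattern, seed=seed)
    aln, table, truth = synth_observed(spec)
    write_ascii_grid(table1_landscape(spec.rows, spec.cols, seed),
                     out / "grid.asc")
    write_locality_csv(table, out / "localities.csv")
    write_fasta(aln, out / "observed.fasta")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return out
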