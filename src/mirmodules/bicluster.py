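"""Bicluster search for miRNA functional modules.

A module is a sub-matrix of the association matrix: a set of miRNAs jointly
and inversely associated with a set of mRNAs (the *direct* arm), optionally
accompanied by positively associated mRNAs (the *indirect* arm, modeling
downstream upregulation).  The objective for a candidate sub-matrix with
rows ``I`` (miRNAs) and columns ``J`` (mRNAs) is the arithmetic mean

    score(I, J) = mean_{i in I, j in J} a_ij

which is minimized: an ideal direct module of perfectly anti-correlated,
site-backed pairs scores −1.  Because the sub-matrix area is held fixed
during the seed search, minimizing the mean is equivalent to maximizing the
number and magnitude of negative cells.

The search runs in two phases, mirroring seed-and-expand biclustering:

1. *Seed search* — simulated annealing over fixed-size sub-matrices.  A
   move swaps one random member row (or column) for a random outside one;
   worse moves are accepted with the Metropolis probability
   ``exp(-Δ/T)`` under a geometric cooling schedule.
2. *Expansion* — deterministic: miRNAs with the most negative mean
   association to the seed mRNAs are added up to ``max_mirnas``, then
   mRNAs are admitted best-first from either arm (most negative mean for
   direct, most positive for indirect) until ``max_mrnas`` is reached.
   Ties break lexicographically by feature id, so expansion is fully
   reproducible.

Successive rounds of :func:`discover_modules` mask the cells of previously
returned seeds so the search favours unexplored structure while still
allowing discovered modules to overlap through expansion.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import InvalidInputError

__all__ = [
    "SAScheduler",
    "SearchConfig",
    "Submatrix",
    "Module",
    "score_submatrix",
    "sa_seed_search",
    "expand_seed",
    "discover_modules",
]


@dataclass(frozen=True)
class SAScheduler:
    """Geometric simulated-annealing schedule.

    ``initial_temp=None`` calibrates the starting temperature from a sample
    of random moves so that roughly 80% of early uphill moves are accepted.
    """

    initial_temp: float | None = None
    cooling: float = 0.95
    moves_per_temp: int = 200
    stop_temp: float = 1e-3

    def __post_init__(self) -> None:
        if not 0.0 < self.cooling < 1.0:
            raise InvalidInputError("cooling factor must be in (0, 1)")
        if self.moves_per_temp < 1 or self.stop_temp <= 0:
            raise InvalidInputError("invalid annealing schedule")


@dataclass(frozen=True)
class SearchConfig:
    """Configuration of the module search.

    ``max_mirnas``/``max_mrnas`` default to 10 and 250, approximating the
    mean number of miRNAs predicted to target an mRNA and the mean number
    of mRNAs targeted per miRNA; ``n_modules`` defaults to 100 discovery
    rounds.  ``min_mean_association`` is the admission floor for expansion
    (0 = any strictly sign-correct candidate is admissible).
    """

    seed_rows: int = 5  # miRNAs per seed
    seed_cols: int = 20  # mRNAs per seed
    max_mirnas: int = 10
    max_mrnas: int = 250
    n_modules: int = 100
    n_restarts: int = 3
    sa_schedule: SAScheduler = field(default_factory=SAScheduler)
    rng_seed: int = 0
    mask_policy: str = "seed-exclusion"
    min_mean_association: float = 0.0

    def __post_init__(self) -> None:
        for name in ("seed_rows", "seed_cols", "max_mirnas", "max_mrnas",
                     "n_restarts"):
            if getattr(self, name) < 1:
                raise InvalidInputError(f"{name} must be positive")
        if self.n_modules < 0:
            raise InvalidInputError("n_modules must be non-negative")
        if self.mask_policy not in ("seed-exclusion", "value-damping"):
            raise InvalidInputError(f"unknown mask policy {self.mask_policy!r}")


@dataclass(frozen=True)
class Submatrix:
    """A fixed set of miRNA rows and mRNA columns of the association matrix."""

    mirnas: tuple[str, ...]
    mrnas: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.mirnas or not self.mrnas:
            raise InvalidInputError("submatrix must have non-empty row and column sets")


@dataclass
class Module:
    """One discovered miRNA functional module.

    ``score`` is the mean association of the direct arm (miRNAs × direct
    mRNAs); ``edges`` holds the per-pair association values of every
    non-zero cell in the module for rendering (negative = direct/red,
    positive = indirect/green).
    """

    mirnas: tuple[str, ...]
    direct_mrnas: tuple[str, ...]
    indirect_mrnas: tuple[str, ...]
    score: float
    seed: Submatrix
    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    module_id: str = ""
    annotation: "object | None" = None

    @property
    def mrnas(self) -> tuple[str, ...]:
        return self.direct_mrnas + self.indirect_mrnas

    @property
    def size(self) -> int:
        return len(self.mirnas) + len(self.direct_mrnas) + len(self.indirect_mrnas)


def _indexers(assoc: pd.DataFrame) -> tuple[dict[str, int], dict[str, int]]:
    return (
        {m: i for i, m in enumerate(assoc.index)},
        {g: j for j, g in enumerate(assoc.columns)},
    )


def score_submatrix(assoc: pd.DataFrame, sub: Submatrix) -> float:
    """Mean association over the sub-matrix (lower is better; ideal = −1)."""
    missing = set(sub.mirnas) - set(assoc.index)
    missing |= set(sub.mrnas) - set(assoc.columns)
    if missing:
        raise InvalidInputError(f"submatrix labels not in matrix: {sorted(missing)[:5]}")
    return float(assoc.loc[list(sub.mirnas), list(sub.mrnas)].to_numpy().mean())


def _initial_temperature(
    values: np.ndarray, rows: np.ndarray, cols: np.ndarray,
    n_rows: int, n_cols: int, rng: np.random.Generator,
    target_accept: float = 0.8, n_probe: int = 100,
) -> float:
    """Temperature at which ~``target_accept`` of sampled uphill moves pass."""
    area = len(rows) * len(cols)
    deltas = []
    row_set, col_set = set(rows.tolist()), set(cols.tolist())
    out_rows = np.array([r for r in range(n_rows) if r not in row_set])
    out_cols = np.array([c for c in range(n_cols) if c not in col_set])
    for _ in range(n_probe):
        if rng.random() < 0.5 and len(out_rows):
            old = rows[rng.integers(len(rows))]
            new = out_rows[rng.integers(len(out_rows))]
            d = (values[new, cols].sum() - values[old, cols].sum()) / area
        elif len(out_cols):
            old = cols[rng.integers(len(cols))]
            new = out_cols[rng.integers(len(out_cols))]
            d = (values[rows, new].sum() - values[rows, old].sum()) / area
        else:
            continue
        if d > 0:
            deltas.append(d)
    if not deltas:
        return 0.1
    return float(np.mean(deltas) / -math.log(target_accept))


def sa_seed_search(
    assoc: pd.DataFrame,
    cfg: SearchConfig,
    rng: np.random.Generator | int | None = None,
) -> Submatrix:
    """Locate a low-mean fixed-size seed sub-matrix by simulated annealing.

    Returns the best state visited during the anneal; reproducible given an
    integer seed or seeded generator.
    """
    values = assoc.to_numpy(float)
    n_rows, n_cols = values.shape
    if n_rows < cfg.seed_rows or n_cols < cfg.seed_cols:
        raise InvalidInputError(
            f"matrix {n_rows}×{n_cols} smaller than seed "
            f"{cfg.seed_rows}×{cfg.seed_cols}"
        )
    rng = np.random.default_rng(rng)
    area = cfg.seed_rows * cfg.seed_cols

    rows = rng.choice(n_rows, size=cfg.seed_rows, replace=False)
    cols = rng.choice(n_cols, size=cfg.seed_cols, replace=False)
    in_row = np.zeros(n_rows, bool)
    in_row[rows] = True
    in_col = np.zeros(n_cols, bool)
    in_col[cols] = True

    score = values[np.ix_(rows, cols)].mean()
    best_score, best_rows, best_cols = score, rows.copy(), cols.copy()

    sched = cfg.sa_schedule
    temp = sched.initial_temp
    if temp is None:
        temp = _initial_temperature(values, rows, cols, n_rows, n_cols, rng)
    temp = max(temp, sched.stop_temp)

    can_move_rows = n_rows > cfg.seed_rows
    can_move_cols = n_cols > cfg.seed_cols
    if not (can_move_rows or can_move_cols):
        return _submatrix_from_indices(assoc, rows, cols)

    while temp > sched.stop_temp:
        for _ in range(sched.moves_per_temp):
            move_row = can_move_rows and (not can_move_cols or rng.random() < 0.5)
            if move_row:
                k = rng.integers(cfg.seed_rows)
                old = rows[k]
                new = int(rng.integers(n_rows))
                if in_row[new]:
                    continue
                delta = (values[new, cols].sum() - values[old, cols].sum()) / area
            else:
                k = rng.integers(cfg.seed_cols)
                old = cols[k]
                new = int(rng.integers(n_cols))
                if in_col[new]:
                    continue
                delta = (values[rows, new].sum() - values[rows, old].sum()) / area
            if delta <= 0 or rng.random() < math.exp(-delta / temp):
                if move_row:
                    in_row[old] = False
                    in_row[new] = True
                    rows[k] = new
                else:
                    in_col[old] = False
                    in_col[new] = True
                    cols[k] = new
                score += delta
                if score < best_score - 1e-15:
                    best_score = score
                    best_rows, best_cols = rows.copy(), cols.copy()
        temp *= sched.cooling
    best_rows, best_cols = _polish(values, best_rows, best_cols)
    return _submatrix_from_indices(assoc, best_rows, best_cols)


def _polish(
    values: np.ndarray, rows: np.ndarray, cols: np.ndarray, max_sweeps: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Alternating exact refinement of a seed.

    For a fixed row set the optimal column set of a mean-minimizing seed is
    simply the ``k`` columns with the smallest column sums (and vice
    versa), so alternating the two exact updates descends to a coordinate-
    wise optimum of the annealed state in a handful of sweeps.
    """
    k_rows, k_cols = len(rows), len(cols)
    for _ in range(max_sweeps):
        new_cols = np.sort(np.argsort(values[rows].sum(axis=0), kind="stable")[:k_cols])
        new_rows = np.sort(np.argsort(values[:, new_cols].sum(axis=1), kind="stable")[:k_rows])
        if np.array_equal(new_rows, np.sort(rows)) and np.array_equal(
            new_cols, np.sort(cols)
        ):
            break
        rows, cols = new_rows, new_cols
    return rows, cols


def _submatrix_from_indices(
    assoc: pd.DataFrame, rows: np.ndarray, cols: np.ndarray
) -> Submatrix:
    # lexicographic member order: deterministic regardless of visit order
    return Submatrix(
        mirnas=tuple(sorted(assoc.index[sorted(rows)])),
        mrnas=tuple(sorted(assoc.columns[sorted(cols)])),
    )


def expand_seed(assoc: pd.DataFrame, seed: Submatrix, cfg: SearchConfig) -> Module:
    """Deterministically grow a seed into a full module.

    miRNAs join by most-negative mean association to the seed mRNAs (up to
    ``cfg.max_mirnas``); mRNAs then join best-first from either arm —
    direct rows by most-negative, indirect rows by most-positive mean
    association to the module's miRNAs — until the combined mRNA count
    reaches ``cfg.max_mrnas``.  Candidates whose mean association is not
    strictly beyond ``cfg.min_mean_association`` in the correct direction
    are never admitted.  Ties break lexicographically by id.
    """
    row_ix, col_ix = _indexers(assoc)
    for m in seed.mirnas:
        if m not in row_ix:
            raise InvalidInputError(f"seed miRNA {m!r} not in matrix")
    for g in seed.mrnas:
        if g not in col_ix:
            raise InvalidInputError(f"seed mRNA {g!r} not in matrix")
    values = assoc.to_numpy(float)
    floor = max(0.0, cfg.min_mean_association)

    mirnas = list(seed.mirnas)
    seed_col_idx = np.array([col_ix[g] for g in seed.mrnas])

    # --- miRNA arm: mean association to the seed's mRNAs ---
    if len(mirnas) < cfg.max_mirnas:
        mean_to_seed = values[:, seed_col_idx].mean(axis=1)
        cands = sorted(
            (
                (mean_to_seed[row_ix[m]], m)
                for m in assoc.index
                if m not in seed.mirnas
            ),
        )
        for mean_a, m in cands:
            if len(mirnas) >= cfg.max_mirnas:
                break
            if mean_a < 0 and -mean_a > floor:
                mirnas.append(m)
            else:
                break  # candidates are sorted: all later ones fail too
        mirnas.sort()

    mir_idx = np.array([row_ix[m] for m in mirnas])
    col_means = values[mir_idx, :].mean(axis=0)

    # --- mRNA arms: interleaved best-first admission ---
    direct = list(seed.mrnas)
    indirect: list[str] = []
    in_module = set(direct)
    heap: list[tuple[float, str, str]] = []  # (-strength, id, arm)
    for g in assoc.columns:
        if g in in_module:
            continue
        mu = col_means[col_ix[g]]
        if mu < 0 and abs(mu) > floor:
            heapq.heappush(heap, (-abs(mu), g, "direct"))
        elif mu > floor:
            heapq.heappush(heap, (-mu, g, "indirect"))
    while heap and len(direct) + len(indirect) < cfg.max_mrnas:
        _, g, arm = heapq.heappop(heap)
        (direct if arm == "direct" else indirect).append(g)

    direct.sort()
    indirect.sort()
    dir_idx = np.array([col_ix[g] for g in direct])
    score = float(values[np.ix_(mir_idx, dir_idx)].mean())

    edges: dict[tuple[str, str], float] = {}
    all_cols = direct + indirect
    sub = assoc.loc[mirnas, all_cols].to_numpy()
    for i, m in enumerate(mirnas):
        for j, g in enumerate(all_cols):
            v = sub[i, j]
            if v != 0.0:
                edges[(m, g)] = float(v)

    return Module(
        mirnas=tuple(mirnas),
        direct_mrnas=tuple(direct),
        indirect_mrnas=tuple(indirect),
        score=score,
        seed=seed,
        edges=edges,
    )


def _apply_mask(
    search_values: np.ndarray,
    seed: Submatrix,
    row_ix: dict[str, int],
    col_ix: dict[str, int],
    policy: str,
) -> None:
    r = np.array([row_ix[m] for m in seed.mirnas])
    c = np.array([col_ix[g] for g in seed.mrnas])
    if policy == "seed-exclusion":
        search_values[np.ix_(r, c)] = 1.0
    else:  # value-damping
        search_values[np.ix_(r, c)] *= 0.5


def discover_modules(assoc: pd.DataFrame, cfg: SearchConfig) -> list[Module]:
    """Run ``cfg.n_modules`` seed-search + expansion rounds.

    Each round takes the best of ``cfg.n_restarts`` independent anneals,
    expands it on the unmasked matrix, then masks the seed cells per
    ``cfg.mask_policy`` so later rounds favour unexplored structure.
    Stops early (with a warning) once no seed with negative score remains.
    Modules are returned ordered by ascending score and labelled
    ``module_001`` onward.
    """
    row_ix, col_ix = _indexers(assoc)
    search = assoc.copy()
    seeds = np.random.SeedSequence(cfg.rng_seed).spawn(cfg.n_modules * cfg.n_restarts)
    modules: list[Module] = []
    for round_i in range(cfg.n_modules):
        best: Submatrix | None = None
        best_score = math.inf
        for r in range(cfg.n_restarts):
            rng = np.random.default_rng(seeds[round_i * cfg.n_restarts + r])
            sub = sa_seed_search(search, cfg, rng)
            s = score_submatrix(search, sub)
            if s < best_score:
                best_score, best = s, sub
        assert best is not None
        if best_score >= 0:
            warnings.warn(
                f"no admissible (negative-score) seed left after "
                f"{len(modules)} of {cfg.n_modules} rounds; stopping early",
                stacklevel=2,
            )
            break
        modules.append(expand_seed(assoc, best, cfg))
        _apply_mask(search.values, best, row_ix, col_ix, cfg.mask_policy)
    modules.sort(key=lambda m: (m.score, m.mirnas))
    for i, m in enumerate(modules, start=1):
        m.module_id = f"module_{i:03d}"
    return modules
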