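"""Cooperativity of miRNA families and genomic clusters.

Members of a miRNA family (shared seed sequence) or genomic cluster
(co-transcribed neighbours) are expected to act cooperatively: an mRNA
targeted by more members of the class should show stronger inverse
expression.  The analysis proceeds per class:

1. every mRNA with at least one predicted site for a class member gets a
   target count ``k`` and an aggregated correlation — the *maximum inverse*
   (i.e. minimum signed) correlation over its targeting members;
2. the median aggregated correlation is taken per level ``k = 1..N``
   (the red trend points of the scatter display);
3. the trend is summarized by Spearman's ρ of the (k, aggregated
   correlation) points, with average ranks over the heavily tied target
   counts — cooperative classes show ρ well below 0;
4. significance comes from an empirical null of randomly drawn miRNA
   groups of the same size (default 100), with the add-one estimator
   ``p = (1 + #{null ρ ≤ observed ρ}) / (1 + n_perm)``.

Genomic clusters are built from loci by single-linkage: two miRNAs link if
they lie within a base-pair window (default 10 kb, gap measured between
interval boundaries) on the same chromosome or share a host gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import InvalidInputError

__all__ = [
    "GenomicLocus",
    "MiRNAGrouping",
    "CooperativityResult",
    "build_genomic_clusters",
    "target_count_profile",
    "cooperativity_trend",
    "cooperativity_pvalue",
    "analyze_groupings",
]


@dataclass(frozen=True)
class GenomicLocus:
    """A miRNA gene location (0-based half-open interval)."""

    mirna_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."
    host_gene: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise InvalidInputError(
                f"malformed interval for {self.mirna_id}: [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class MiRNAGrouping:
    """A named miRNA family or genomic cluster."""

    name: str
    kind: str  # "family" | "genomic_cluster"
    members: frozenset[str]

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass
class CooperativityResult:
    grouping: MiRNAGrouping
    levels: list[int]
    medians: list[float]
    rho: float  # NaN = undefined
    p_value: float  # NaN = undefined
    n_permutations: int
    null_rhos: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


def _gap(a: GenomicLocus, b: GenomicLocus) -> int:
    """Base pairs between two intervals (0 when they touch or overlap)."""
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def build_genomic_clusters(
    loci: list[GenomicLocus], window: int = 10_000
) -> list[MiRNAGrouping]:
    """Group miRNAs into genomic clusters by single-linkage chaining.

    Two loci link when on the same chromosome within ``window`` bp, or when
    they share a host gene (regardless of distance); the transitive closure
    of links defines the clusters.  Only groups of ≥2 members are returned,
    each named after its first member in genomic order.
    """
    ids = [loc.mirna_id for loc in loci]
    if len(set(ids)) != len(ids):
        raise InvalidInputError("duplicate miRNA ids in loci")

    parent = list(range(len(loci)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            a, b = loci[i], loci[j]
            linked = a.chromosome == b.chromosome and _gap(a, b) <= window
            if not linked and a.host_gene is not None:
                linked = a.host_gene == b.host_gene
            if linked:
                union(i, j)

    groups: dict[int, list[GenomicLocus]] = {}
    for i, loc in enumerate(loci):
        groups.setdefault(find(i), []).append(loc)

    out = []
    for members in groups.values():
        if len(members) < 2:
            continue
        members.sort(key=lambda l: (l.chromosome, l.start, l.mirna_id))
        out.append(
            MiRNAGrouping(
                name=f"{members[0].mirna_id} cluster",
                kind="genomic_cluster",
                members=frozenset(l.mirna_id for l in members),
            )
        )
    out.sort(key=lambda g: g.name)
    return out


def target_count_profile(
    corr: pd.DataFrame,
    targets: pd.DataFrame,
    group: MiRNAGrouping,
) -> pd.DataFrame:
    """Per-mRNA target count and aggregated (max-inverse) correlation.

    For every mRNA predicted to be targeted by ≥1 group member, returns the
    number of targeting members ``k`` and the minimum signed (most
    negative, i.e. maximum inverse) correlation over those members.
    mRNAs targeted by no member are excluded; an empty profile is returned
    (not an error) when the group has no targets in the matrix.
    """
    members = sorted(group.members & set(corr.index) & set(targets.index))
    if len(members) != group.n:
        missing = sorted(group.members - set(members))
        raise InvalidInputError(
            f"group {group.name!r} members absent from matrices: {missing[:5]}"
        )
    cols = corr.columns.intersection(targets.columns)
    t = targets.loc[members, cols].to_numpy(bool)
    c = corr.loc[members, cols].to_numpy(float)
    k = t.sum(axis=0)
    masked = np.where(t, c, np.inf)
    with np.errstate(invalid="ignore"):
        agg = masked.min(axis=0)
    sel = k > 0
    return pd.DataFrame(
        {"k": k[sel].astype(int), "correlation": agg[sel]},
        index=cols[sel],
    )


def cooperativity_trend(
    profile: pd.DataFrame,
) -> tuple[list[int], list[float], float]:
    """Per-level medians and the Spearman ρ of the full profile.

    Medians (the red trend points of the scatter display) are returned per
    populated level.  ρ is the Spearman rank correlation of all
    (target count, aggregated correlation) points — the target counts are
    heavily tied, so average ranks apply.  ρ is NaN (undefined) with fewer
    than 3 populated levels or when all correlations tie.
    """
    if profile.empty:
        raise InvalidInputError("empty target-count profile")
    clean = profile.dropna(subset=["correlation"])
    med = clean.groupby("k")["correlation"].median().sort_index()
    levels = [int(k) for k in med.index]
    medians = [float(v) for v in med.values]
    if len(levels) < 3 or clean["correlation"].nunique() == 1:
        return levels, medians, float("nan")
    rho = stats.spearmanr(clean["k"], clean["correlation"]).statistic
    return levels, medians, float(rho)


def _trend_rho(
    c: np.ndarray, t: np.ndarray, member_idx: np.ndarray
) -> float:
    """Profile trend ρ for a member index set (vectorized hot path)."""
    tm = t[member_idx]
    k = tm.sum(axis=0)
    sel = k > 0
    if not sel.any():
        return float("nan")
    agg = np.where(tm[:, sel], c[member_idx][:, sel], np.inf).min(axis=0)
    ks = k[sel]
    ok = np.isfinite(agg)
    ks, agg = ks[ok], agg[ok]
    if ks.size == 0 or np.unique(ks).size < 3 or np.ptp(agg) == 0:
        return float("nan")
    return float(stats.spearmanr(ks, agg).statistic)


def cooperativity_pvalue(
    corr: pd.DataFrame,
    targets: pd.DataFrame,
    group: MiRNAGrouping,
    n_perm: int = 100,
    rng: np.random.Generator | int | None = None,
) -> CooperativityResult:
    """Empirical significance of a class's cooperativity trend.

    The null draws ``n_perm`` uniform random miRNA subsets of the same size
    from the matrix's miRNA set and recomputes the trend ρ for each;
    ``p = (1 + #{null ρ ≤ observed}) / (1 + n_perm)``.  Null draws whose ρ
    is undefined never count as ≤ observed (conservative).
    """
    if n_perm < 1:
        raise InvalidInputError("n_perm must be ≥ 1")
    rng = np.random.default_rng(rng)

    profile = target_count_profile(corr, targets, group)
    if profile.empty:
        return CooperativityResult(group, [], [], float("nan"), float("nan"), n_perm)
    levels, medians, rho = cooperativity_trend(profile)

    cols = corr.columns.intersection(targets.columns)
    all_mirnas = corr.index.intersection(targets.index)
    if len(all_mirnas) < group.n:
        raise InvalidInputError(
            f"cannot draw null groups of size {group.n} from "
            f"{len(all_mirnas)} miRNAs"
        )
    c = corr.loc[all_mirnas, cols].to_numpy(float)
    t = targets.loc[all_mirnas, cols].to_numpy(bool)

    null_rhos = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.choice(len(all_mirnas), size=group.n, replace=False)
        null_rhos[b] = _trend_rho(c, t, idx)

    if math.isnan(rho):
        p = float("nan")
    else:
        exceed = int(np.sum(null_rhos[~np.isnan(null_rhos)] <= rho))
        p = (1 + exceed) / (1 + n_perm)
    return CooperativityResult(group, levels, medians, rho, p, n_perm, null_rhos)


def analyze_groupings(
    corr: pd.DataFrame,
    targets: pd.DataFrame,
    groups: list[MiRNAGrouping],
    n_perm: int = 100,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Cooperativity table (name, kind, n, rho, p) over a list of classes."""
    rng = np.random.default_rng(rng)
    rows = []
    for g in groups:
        res = cooperativity_pvalue(corr, targets, g, n_perm=n_perm, rng=rng)
        rows.append(
            {"name": g.name, "kind": g.kind, "n": g.n,
             "rho": res.rho, "p": res.p_value}
        )
    return pd.DataFrame(rows)
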