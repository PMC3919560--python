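"""Module-map visualization: overlap similarity, classical MDS, bubble plot.

Biclusters are hard to visualize because modules share members and live on
different feature subsets.  The approach here renders the whole module set
as a 2-D bubble chart:

* pairwise module similarity is measured separately on the miRNA side and
  the mRNA side with the overlap metric ``s(L1, L2) = |L1 ∩ L2| /
  max(|L1|, |L2|)``, whose complement ``1 − s`` is a metric (it obeys the
  triangle inequality), so the similarities embed faithfully;
* classical (Torgerson) multidimensional scaling projects each similarity
  matrix onto one axis — X for miRNA overlap, Y for mRNA overlap;
* each module is drawn as a bubble whose radius is proportional to the
  enriched fraction of its top annotation term, coloured by a
  (perimeter, area) palette pair so a palette of 10 colours distinguishes
  up to 100 terms, with larger modules drawn behind smaller ones.

Per-module bipartite graphs (red = inverse/direct edges, green =
positive/indirect) can be exported to GraphML for external viewers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .association import InvalidInputError
from .bicluster import Module

__all__ = [
    "overlap",
    "similarity_matrices",
    "classical_mds",
    "ModuleLayout",
    "layout_modules",
    "plot_layout",
    "module_graph",
    "export_module_graph",
]

logger = logging.getLogger(__name__)

OTHER_TERM = "other"


def overlap(L1: set[str], L2: set[str], denominator: str = "max") -> float:
    """Similarity of two label lists in [0, 1].

    ``max`` (default) divides the intersection by the larger list, which
    avoids the size bias of a min denominator and makes ``1 − s`` a
    metric; ``union`` gives the Jaccard index instead.
    """
    if not L1 or not L2:
        raise InvalidInputError("overlap of an empty list is undefined")
    inter = len(set(L1) & set(L2))
    if denominator == "max":
        return inter / max(len(set(L1)), len(set(L2)))
    if denominator == "union":
        return inter / len(set(L1) | set(L2))
    raise InvalidInputError(f"unknown denominator {denominator!r}")


def similarity_matrices(
    modules: list[Module], denominator: str = "max"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise miRNA-side and mRNA-side overlap similarity of modules.

    The mRNA side uses the combined direct ∪ indirect arms.  Returns two
    symmetric unit-diagonal DataFrames indexed by module id.
    """
    if len(modules) < 2:
        raise InvalidInputError("need at least 2 modules for similarity matrices")
    ids = [m.module_id or f"module_{i:03d}" for i, m in enumerate(modules, 1)]
    mirna_sets = [set(m.mirnas) for m in modules]
    mrna_sets = [set(m.mrnas) for m in modules]

    def matrix(sets: list[set[str]]) -> pd.DataFrame:
        n = len(sets)
        vals = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                vals[i, j] = vals[j, i] = overlap(sets[i], sets[j], denominator)
        return pd.DataFrame(vals, index=ids, columns=ids)

    return matrix(mirna_sets), matrix(mrna_sets)


def classical_mds(similarity: pd.DataFrame, dims: int = 1) -> pd.DataFrame:
    """Classical (Torgerson) MDS of a similarity matrix.

    Distances ``d = 1 − s`` are squared and double-centered,
    ``B = −½ J d² J``; the top ``dims`` eigenpairs give the coordinates,
    with negative eigenvalues (non-Euclidean residue) clipped to zero.
    Sign convention per dimension: the entry of largest magnitude is made
    positive, so coordinates are reflection-stable.  All-identical modules
    map to all-zero coordinates.
    """
    s = similarity.to_numpy(float)
    if s.shape[0] != s.shape[1] or not np.allclose(s, s.T):
        raise InvalidInputError("similarity matrix must be square and symmetric")
    n = s.shape[0]
    d2 = (1.0 - s) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:dims]
    lam = np.clip(eigval[order], 0.0, None)
    coords = eigvec[:, order] * np.sqrt(lam)
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col.any():
            peak = np.argmax(np.abs(np.round(col, 12)))
            if col[peak] < 0:
                coords[:, k] = -col
    return pd.DataFrame(
        coords, index=similarity.index, columns=[f"dim{k+1}" for k in range(dims)]
    )


@dataclass
class ModuleLayout:
    """One bubble of the module map."""

    module_id: str
    x: float
    y: float
    radius: float
    term: str
    fraction: float
    perimeter_color: int
    area_color: int
    z_rank: int  # 0 drawn first (backmost); larger modules get lower ranks


def layout_modules(
    modules: list[Module],
    palette_size: int = 10,
    r_min: float = 0.0,
    r_max: float = 1.0,
    denominator: str = "max",
) -> list[ModuleLayout]:
    """Compute the 2-D bubble layout of an annotated module set.

    X positions come from miRNA-overlap MDS, Y from mRNA-overlap MDS.
    Radius maps the top-term enriched fraction linearly onto
    ``(r_min, r_max]``; colours are (perimeter, area) palette index pairs
    assigned to terms in order of first appearance, with terms beyond
    ``palette_size**2`` collapsed to a shared "other" colour.
    """
    sim_mir, sim_mrna = similarity_matrices(modules, denominator)
    x = classical_mds(sim_mir, dims=1)["dim1"]
    y = classical_mds(sim_mrna, dims=1)["dim1"]

    terms: list[str] = []
    for m in modules:
        t = m.annotation.top_term if m.annotation else OTHER_TERM
        if t not in terms:
            terms.append(t)
    capacity = palette_size * palette_size
    if len(terms) > capacity:
        logger.warning(
            "%d distinct terms exceed the %d-colour capacity; extra terms "
            "share the %r colour", len(terms), capacity, OTHER_TERM,
        )
    color_of = {t: i for i, t in enumerate(terms[:capacity])}

    order = sorted(range(len(modules)), key=lambda i: -modules[i].size)
    z_rank = {i: r for r, i in enumerate(order)}

    layouts = []
    for i, m in enumerate(modules):
        mid = sim_mir.index[i]
        frac = m.annotation.fraction if m.annotation else 0.0
        term = m.annotation.top_term if m.annotation else OTHER_TERM
        code = color_of.get(term, capacity - 1 if terms else 0)
        radius = r_min + frac * (r_max - r_min)
        if radius <= 0:
            radius = max(r_max * 1e-3, 1e-6)  # invariant: radius strictly > 0
        layouts.append(
            ModuleLayout(
                module_id=str(mid),
                x=float(x.loc[mid]),
                y=float(y.loc[mid]),
                radius=radius,
                term=term,
                fraction=frac,
                perimeter_color=code // palette_size,
                area_color=code % palette_size,
                z_rank=z_rank[i],
            )
        )
    return layouts


def plot_layout(layouts: list[ModuleLayout], path: str, palette: str = "tab10") -> None:
    """Render the bubble chart to a vector/raster figure file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cmap = plt.get_cmap(palette)
    fig, ax = plt.subplots(figsize=(7, 6))
    for lay in sorted(layouts, key=lambda l: l.z_rank):
        ax.scatter(
            [lay.x], [lay.y],
            s=max(20.0, 4000.0 * lay.radius**2),
            facecolor=cmap(lay.area_color % cmap.N),
            edgecolor=cmap(lay.perimeter_color % cmap.N),
            linewidths=1.5,
            alpha=0.85,
        )
    ax.set_xlabel("miRNA overlap (classical MDS)")
    ax.set_ylabel("mRNA overlap (classical MDS)")
    ax.set_title("miRNA-mRNA functional modules")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def module_graph(
    module: Module, neg_threshold: float = 0.0, pos_threshold: float = 0.0
) -> nx.Graph:
    """Bipartite miRNA-mRNA graph of one module.

    Edges carry ``sign`` ("direct" for inverse associations, "indirect"
    for positive) and ``weight`` = |association|; edges whose magnitude
    falls below the sign-specific threshold are omitted.
    """
    if not 0.0 <= neg_threshold <= 1.0 or not 0.0 <= pos_threshold <= 1.0:
        raise InvalidInputError("thresholds must be in [0, 1]")
    g = nx.Graph(module_id=module.module_id, score=module.score)
    for m in module.mirnas:
        g.add_node(m, bipartite="mirna")
    for t in module.mrnas:
        g.add_node(t, bipartite="mrna")
    n_edges = 0
    for (m, t), a in sorted(module.edges.items()):
        thr = neg_threshold if a < 0 else pos_threshold
        if abs(a) >= thr and a != 0:
            g.add_edge(m, t, weight=abs(a),
                       sign="direct" if a < 0 else "indirect",
                       association=a)
            n_edges += 1
    if n_edges == 0:
        warnings.warn(
            f"thresholds ({neg_threshold}, {pos_threshold}) exclude every "
            f"edge of {module.module_id or 'module'}", stacklevel=2,
        )
    return g


def export_module_graph(
    module: Module,
    path: str,
    neg_threshold: float = 0.0,
    pos_threshold: float = 0.0,
) -> nx.Graph:
    """Write the thresholded module graph to GraphML and return it."""
    g = module_graph(module, neg_threshold, pos_threshold)
    nx.write_graphml(g, path)
    return g
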