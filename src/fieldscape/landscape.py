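"""The 2-D topic landscape.

Articles are embedded from their k-dimensional topic mixtures into the
plane with exact t-SNE on pairwise Hellinger distances, and each
field's article density is estimated on a common G x G lattice with a
product-Gaussian kernel (Scott's rule bandwidth per axis).  The field
boundary is the set of well-populated cells where the two densities
are within a factor e^eps of each other — where articles are evenly
distributed between the fields.  Densities may be weighted, e.g. by
each article's cross-field citation count, to map where one field's
work attracts the other's attention.  Journal-level structure comes
from average-linkage clustering of journal x topic median profiles
under Hellinger distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.manifold import TSNE

from .field_bias import lower_median


def hellinger_distance(p, q) -> float:
    """sqrt(1 − Σ sqrt(p q)) for two probability vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if (p < 0).any() or (q < 0).any():
        raise ValueError("negative entries in probability vector")
    if not (np.isclose(p.sum(), 1.0, atol=1e-8) and np.isclose(q.sum(), 1.0, atol=1e-8)):
        raise ValueError("inputs must each sum to 1")
    bc = np.sqrt(p * q).sum()
    return float(np.sqrt(max(0.0, 1.0 - min(bc, 1.0))))


def hellinger_matrix(theta: np.ndarray) -> np.ndarray:
    """Pairwise Hellinger distances between θ rows (symmetric, zero diag)."""
    root = np.sqrt(np.asarray(theta, dtype=float))
    bc = np.clip(root @ root.T, 0.0, 1.0)
    d = np.sqrt(np.clip(1.0 - bc, 0.0, None))
    np.fill_diagonal(d, 0.0)
    return d


def embed_2d(theta: np.ndarray, perplexity: float = 30.0, seed: int = 0,
             n_iter: int = 1000, metric: str = "hellinger") -> np.ndarray:
    """Exact t-SNE of θ rows to 2-D.

    Input affinities come from pairwise Hellinger distances by default
    (Euclidean switchable); the run is deterministic under ``seed``.
    """
    theta = np.asarray(theta, dtype=float)
    D = theta.shape[0]
    if D < 3 * perplexity:
        raise ValueError(f"perplexity {perplexity} infeasible for {D} articles (need D >= 3*perplexity)")
    if metric == "hellinger":
        dist = hellinger_matrix(theta)
        tsne = TSNE(n_components=2, metric="precomputed", method="exact",
                    init="random", random_state=seed, perplexity=perplexity,
                    max_iter=n_iter, early_exaggeration=12.0, learning_rate=200.0)
        return np.asarray(tsne.fit_transform(dist))
    if metric == "euclidean":
        tsne = TSNE(n_components=2, metric="euclidean", method="exact",
                    init="random", random_state=seed, perplexity=perplexity,
                    max_iter=n_iter, early_exaggeration=12.0, learning_rate=200.0)
        return np.asarray(tsne.fit_transform(theta))
    raise ValueError("metric must be 'hellinger' or 'euclidean'")


def grid_extent(coords: np.ndarray, pad: float = 0.05):
    """Bounding box of all coordinates padded by a fraction per side."""
    coords = np.asarray(coords, dtype=float)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return (lo[0] - pad * span[0], hi[0] + pad * span[0],
            lo[1] - pad * span[1], hi[1] + pad * span[1])


@dataclass
class LandscapeGrid:
    """One density surface on a shared lattice."""

    density: np.ndarray        # G x G, rows indexed by y, columns by x
    extent: tuple              # (xmin, xmax, ymin, ymax)
    bandwidth: tuple           # (hx, hy)
    label: str = ""

    @property
    def cell_area(self) -> float:
        g = self.density.shape
        xmin, xmax, ymin, ymax = self.extent
        return ((xmax - xmin) / g[1]) * ((ymax - ymin) / g[0])

    def cell_centers(self):
        xmin, xmax, ymin, ymax = self.extent
        gy, gx = self.density.shape
        xs = xmin + (np.arange(gx) + 0.5) * (xmax - xmin) / gx
        ys = ymin + (np.arange(gy) + 0.5) * (ymax - ymin) / gy
        return xs, ys


def scott_bandwidth(points: np.ndarray) -> tuple:
    """Per-axis Scott's rule: σ_d n^(−1/(d+4)) with d = 2."""
    n = points.shape[0]
    sd = points.std(axis=0, ddof=1) if n > 1 else np.zeros(2)
    factor = n ** (-1.0 / 6.0)
    return float(sd[0] * factor), float(sd[1] * factor)


def density_grid(coords: np.ndarray, subset=None, bandwidth=None, G: int = 200,
                 extent=None, weights=None, label: str = "") -> LandscapeGrid:
    """Product-Gaussian KDE evaluated on a G x G lattice.

    The surface is normalized to integrate to 1 over the grid
    (cell-sum x cell-area = 1).  A singleton subset falls back to a
    bandwidth of 5% of the extent per axis.
    """
    coords = np.asarray(coords, dtype=float)
    pts = coords if subset is None else coords[np.asarray(subset)]
    if pts.shape[0] == 0:
        raise ValueError("empty subset")
    if extent is None:
        extent = grid_extent(coords)
    xmin, xmax, ymin, ymax = extent
    if weights is None:
        w = np.full(pts.shape[0], 1.0 / pts.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if subset is not None:
            w = w[np.asarray(subset)]
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        if w.sum() == 0:
            raise ValueError("weights must not all be zero")
        w = w / w.sum()
    if bandwidth is None:
        hx, hy = scott_bandwidth(pts)
        if hx <= 0 or hy <= 0:
            warnings.warn("degenerate spread: bandwidth fallback to 5% of extent")
            hx = max(hx, 0.05 * (xmax - xmin))
            hy = max(hy, 0.05 * (ymax - ymin))
    else:
        hx, hy = (bandwidth, bandwidth) if np.isscalar(bandwidth) else bandwidth
    xs = xmin + (np.arange(G) + 0.5) * (xmax - xmin) / G
    ys = ymin + (np.arange(G) + 0.5) * (ymax - ymin) / G
    # separable kernel: weighted outer product of per-axis Gaussians
    gx = np.exp(-0.5 * ((xs[None, :] - pts[:, 0:1]) / hx) ** 2) / (hx * np.sqrt(2 * np.pi))
    gy = np.exp(-0.5 * ((ys[None, :] - pts[:, 1:2]) / hy) ** 2) / (hy * np.sqrt(2 * np.pi))
    dens = (gy * w[:, None]).T @ gx     # rows = y, cols = x
    grid = LandscapeGrid(density=dens, extent=extent, bandwidth=(hx, hy), label=label)
    total = grid.density.sum() * grid.cell_area
    if total <= 0:
        raise ValueError("zero density mass on grid")
    grid.density = grid.density / total
    return grid


def weighted_density(coords: np.ndarray, weights, bandwidth=None, G: int = 200,
                     extent=None, label: str = "") -> LandscapeGrid:
    """KDE with per-point weights normalized to sum 1."""
    return density_grid(coords, bandwidth=bandwidth, G=G, extent=extent,
                        weights=weights, label=label)


def field_boundary(grid_eco: LandscapeGrid, grid_cons: LandscapeGrid,
                   density_floor: float | None = None,
                   eps: float = float(np.log(1.5))) -> pd.DataFrame:
    """Cells where the two fields' densities are nearly equal.

    A cell qualifies when total density >= density_floor (default 5% of
    the max total density) and |log(d_eco / d_cons)| <= eps.  Cells are
    returned with a connected-component label, ordered by component
    then row-major position.
    """
    if grid_eco.density.shape != grid_cons.density.shape:
        raise ValueError("grids must share a lattice")
    total = grid_eco.density + grid_cons.density
    if density_floor is None:
        density_floor = 0.05 * total.max()
    with np.errstate(divide="ignore", invalid="ignore"):
        logratio = np.log(grid_eco.density) - np.log(grid_cons.density)
    mask = (total >= density_floor) & (np.abs(logratio) <= eps)
    if not mask.any():
        warnings.warn("no boundary cells qualify")
        return pd.DataFrame(columns=["component", "row", "col", "x", "y"])
    labeled, n_comp = ndimage.label(mask)
    xs, ys = grid_eco.cell_centers()
    rows = []
    for comp in range(1, n_comp + 1):
        rr, cc = np.nonzero(labeled == comp)
        for r, c in sorted(zip(rr, cc)):
            rows.append({"component": comp, "row": int(r), "col": int(c),
                         "x": float(xs[c]), "y": float(ys[r])})
    return pd.DataFrame(rows)


DEFAULT_PERIODS = ((2000, 2004), (2005, 2009), (2010, 2014))


def period_landscapes(coords: np.ndarray, field_labels, years,
                      periods=DEFAULT_PERIODS, G: int = 200,
                      bandwidth=None) -> list[LandscapeGrid]:
    """Per-period, per-field density surfaces on one shared embedding
    and extent.  Period bounds are inclusive at both ends."""
    years = np.asarray(years)
    labels = np.asarray(field_labels)
    assigned = np.zeros(len(years), dtype=bool)
    for lo, hi in periods:
        assigned |= (years >= lo) & (years <= hi)
    if not assigned.all():
        raise ValueError("every article's year must fall in some period")
    extent = grid_extent(coords)
    grids = []
    for lo, hi in periods:
        for f in sorted(set(labels)):
            mask = (years >= lo) & (years <= hi) & (labels == f)
            if not mask.any():
                warnings.warn(f"period {lo}-{hi} field {f}: empty, surface omitted")
                continue
            grids.append(density_grid(coords, subset=mask, G=G, extent=extent,
                                      bandwidth=bandwidth, label=f"{lo}-{hi}:{f}"))
    return grids


@dataclass
class JournalTopicMatrix:
    """Journal x topic median log10 θ with hierarchical orderings."""

    matrix: pd.DataFrame
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list
    col_order: list
    flagged_journals: list


def cluster_journal_topics(theta: np.ndarray, journal_labels) -> JournalTopicMatrix:
    """Median log10 topic profile per journal, with rows and columns
    clustered by average linkage on Hellinger distances of the
    renormalized (linear-scale) median profiles."""
    theta = np.asarray(theta, dtype=float)
    journals = np.asarray(journal_labels)
    names = sorted(set(journals))
    if len(names) < 2:
        raise ValueError("need at least 2 journals")
    flagged = []
    profiles = []
    for j in names:
        mask = journals == j
        if mask.sum() < 3:
            flagged.append(j)
        logt = np.log10(theta[mask])
        profiles.append([lower_median(logt[:, t]) for t in range(theta.shape[1])])
    mat = pd.DataFrame(profiles, index=pd.Index(names, name="journal"),
                       columns=pd.RangeIndex(theta.shape[1], name="topic"))

    def _helldist(rows: np.ndarray) -> np.ndarray:
        lin = 10.0 ** rows
        lin = lin / lin.sum(axis=1, keepdims=True)
        root = np.sqrt(lin)
        bc = np.clip(root @ root.T, 0.0, 1.0)
        d = np.sqrt(np.clip(1.0 - bc, 0.0, None))
        np.fill_diagonal(d, 0.0)
        return d

    row_d = _helldist(mat.values)
    col_d = _helldist(mat.values.T)
    row_link = linkage(squareform(row_d, checks=False), method="average")
    col_link = linkage(squareform(col_d, checks=False), method="average")
    return JournalTopicMatrix(
        matrix=mat,
        row_linkage=row_link,
        col_linkage=col_link,
        row_order=[names[i] for i in leaves_list(row_link)],
        col_order=[int(i) for i in leaves_list(col_link)],
        flagged_journals=flagged,
    )
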