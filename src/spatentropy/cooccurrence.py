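"""Co-occurrence tables and distance-based entropy measures.

The base categorical variable X with I categories induces a couple variable
Z with I^2 ordered categories.  Couples are collected either under rook
contiguity on a grid (O'Neill's entropy, the relative contagion index,
Parresol and Edwards' entropy) or within a chosen Euclidean distance d
(Leibovici's entropy, applicable to both marked points and grids).

Enumeration conventions
-----------------------
* Contiguity: every rook-adjacent pair of valid cells is visited exactly
  once by scanning each cell's east and north neighbour; the ordered couple
  is (scan-origin category, neighbour category).  Pairs touching a NODATA
  cell do not exist.
* Distance rule: every unordered pair {i, j} with distance <= d is counted
  once, with i preceding j in the canonical order (ascending x, then y,
  then input order); the recorded ordered couple is (category_i,
  category_j).  "Within d" is inclusive, so on a square-cell grid d = cell
  size reproduces the contiguity pair multiset exactly.
* An optional ``symmetrise`` flag splits each mixed ordered count equally
  between a-b and b-a.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .errors import EmptyTableError, ParameterError
from .geometry import CategoricalRaster, PointPattern
from .results import EntropyResult
from .shannon import entropy_nats

__all__ = [
    "CooccurrenceTable",
    "DistanceSummary",
    "contiguous_couples",
    "distance_couples",
    "oneill_entropy",
    "contagion",
    "parresol_edwards",
    "leibovici_entropy",
    "distance_summaries",
    "distance_sweep",
]


@dataclass
class CooccurrenceTable:
    """Counts of the I^2 ordered couples of categories under a spatial rule."""

    categories: list
    counts: np.ndarray  # (I, I); counts[a, b] = count of couple a-b
    rule: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        I = len(self.categories)
        if self.counts.shape != (I, I):
            raise ParameterError("couple counts must be an I x I matrix")
        if (self.counts < 0).any():
            raise ParameterError("couple counts must be non-negative")

    @classmethod
    def from_counts(cls, categories, counts, rule: dict | None = None
                    ) -> "CooccurrenceTable":
        """Build a table from a flat length-I^2 vector in row-major couple order."""
        categories = list(categories)
        I = len(categories)
        counts = np.asarray(counts, dtype=float).reshape(I, I)
        return cls(categories, counts, rule or {})

    @property
    def I(self) -> int:  # noqa: E743
        return len(self.categories)

    @property
    def total_pairs(self) -> float:
        return float(self.counts.sum())

    @property
    def probs(self) -> np.ndarray:
        total = self.counts.sum()
        if total <= 0:
            raise EmptyTableError("co-occurrence table is empty")
        return self.counts / total

    @property
    def couple_labels(self) -> list[str]:
        return [f"{a}-{b}" for a in self.categories for b in self.categories]

    def symmetrised(self) -> "CooccurrenceTable":
        """Split each mixed ordered count equally between a-b and b-a."""
        sym = (self.counts + self.counts.T) / 2.0
        rule = dict(self.rule, symmetrised=True)
        return CooccurrenceTable(self.categories, sym, rule)

    def to_records(self) -> list[dict]:
        total = self.counts.sum()
        recs = []
        for i, a in enumerate(self.categories):
            for j, b in enumerate(self.categories):
                c = self.counts[i, j]
                recs.append({"couple": f"{a}-{b}", "count": float(c),
                             "prob": float(c / total) if total else 0.0})
        return recs


# ---------------------------------------------------------------------------
# Table construction
# ---------------------------------------------------------------------------


def _category_codes(values, categories=None):
    if categories is None:
        seen: dict = {}
        for v in values:
            seen.setdefault(v, None)
        categories = list(seen)
    lookup = {c: i for i, c in enumerate(categories)}
    codes = np.array([lookup[v] for v in values], dtype=np.int64)
    return categories, codes


def contiguous_couples(raster: CategoricalRaster,
                       symmetrise: bool = False) -> CooccurrenceTable:
    """Ordered couples of rook-adjacent valid cells, each adjacency once."""
    valid = ~raster.mask
    cats, _ = _category_codes(raster.valid_values())
    lookup = {c: i for i, c in enumerate(cats)}
    code_grid = np.full(raster.values.shape, -1, dtype=np.int64)
    vals = raster.values[valid]
    code_grid[valid] = np.array([lookup[v] for v in vals], dtype=np.int64)

    I = len(cats)
    counts = np.zeros((I, I), dtype=np.int64)
    # east neighbour
    a = code_grid[:, :-1]
    b = code_grid[:, 1:]
    ok = (a >= 0) & (b >= 0)
    if ok.any():
        counts += np.bincount((a[ok] * I + b[ok]).ravel(),
                              minlength=I * I).reshape(I, I)
    # north neighbour (row + 1; row 0 is the southernmost)
    a = code_grid[:-1, :]
    b = code_grid[1:, :]
    ok = (a >= 0) & (b >= 0)
    if ok.any():
        counts += np.bincount((a[ok] * I + b[ok]).ravel(),
                              minlength=I * I).reshape(I, I)
    if counts.sum() == 0:
        raise EmptyTableError("raster has no adjacencies between valid cells")
    table = CooccurrenceTable(cats, counts, {"rule": "contiguity"})
    return table.symmetrised() if symmetrise else table


def _coords_and_values(data):
    """(coords, values, kind) for a marked pattern or a raster."""
    if isinstance(data, PointPattern):
        if data.marks is None:
            raise ParameterError("distance couples on points require marks")
        return data.coords, data.marks, "points"
    if isinstance(data, CategoricalRaster):
        return data.valid_centroids(), data.valid_values(), "grid"
    raise ParameterError(f"unsupported data type {type(data).__name__}")


def _canonical_order(coords: np.ndarray) -> np.ndarray:
    """Indices sorting by ascending x, then y, then input order (stable)."""
    return np.lexsort((coords[:, 1], coords[:, 0]))


def distance_couples(data, d: float,
                     symmetrise: bool = False) -> CooccurrenceTable:
    """Ordered couples over unordered pairs within distance d (inclusive).

    Each pair {i, j} is counted once; the couple is (category_i,
    category_j) with i preceding j in the canonical coordinate order.
    """
    if d <= 0:
        raise ParameterError("distance d must be positive")
    coords, values, kind = _coords_and_values(data)
    if len(coords) < 2:
        raise ParameterError("need at least two observations")
    order = _canonical_order(coords)
    coords = coords[order]
    cats, codes = _category_codes(np.asarray(values, dtype=object)[order])
    I = len(cats)

    tree = cKDTree(coords)
    pairs = tree.query_pairs(d, output_type="ndarray")  # i < j in sorted index
    counts = np.zeros((I, I), dtype=np.int64)
    if len(pairs):
        ci = codes[pairs[:, 0]]
        cj = codes[pairs[:, 1]]
        counts = np.bincount(ci * I + cj, minlength=I * I).reshape(I, I)
    if counts.sum() == 0:
        dmin = float(tree.query(coords, k=2)[0][:, 1].min())
        raise EmptyTableError(
            f"no pair lies within d={d}; minimum interpoint distance is {dmin}",
            min_distance=dmin)
    table = CooccurrenceTable(cats, counts,
                              {"rule": "distance", "d": float(d),
                               "data_kind": kind})
    return table.symmetrised() if symmetrise else table


# ---------------------------------------------------------------------------
# Entropy measures on couple tables
# ---------------------------------------------------------------------------


def _couple_entropy(table: CooccurrenceTable, measure: str) -> EntropyResult:
    if table.total_pairs <= 0:
        raise EmptyTableError("co-occurrence table is empty")
    h = entropy_nats(table.probs.ravel())
    hmax = float(np.log(table.I ** 2))
    relative = h / hmax if hmax > 0 else 1.0
    return EntropyResult(measure=measure, value=h, range_min=0.0,
                         range_max=hmax, relative=relative, table=table,
                         meta={"I": table.I, "total_pairs": table.total_pairs,
                               **table.rule})


def oneill_entropy(table) -> EntropyResult:
    """O'Neill's entropy over contiguous-couple frequencies; range [0, ln I^2]."""
    if isinstance(table, CategoricalRaster):
        table = contiguous_couples(table)
    if table.rule.get("rule", "contiguity") != "contiguity":
        raise ParameterError("O'Neill's entropy requires a contiguity-rule table")
    return _couple_entropy(table, "oneill")


def contagion(table) -> EntropyResult:
    """Relative contagion index, 1 minus the relative O'Neill entropy."""
    res = oneill_entropy(table)
    value = 1.0 - res.relative
    return EntropyResult(measure="contagion", value=value, range_min=0.0,
                         range_max=1.0, relative=value, table=res.table,
                         meta=res.meta, units="")


def parresol_edwards(table) -> EntropyResult:
    """Parresol and Edwards' entropy, the negative of O'Neill's entropy.

    Its relative form coincides with O'Neill's relative entropy.
    """
    res = oneill_entropy(table)
    return EntropyResult(measure="parresol_edwards", value=-res.value,
                         range_min=-res.range_max, range_max=0.0,
                         relative=res.relative, table=res.table, meta=res.meta)


def leibovici_entropy(data, d: float | None = None,
                      symmetrise: bool = False) -> EntropyResult:
    """Leibovici's entropy over couples within distance d; range [0, ln I^2]."""
    if isinstance(data, CooccurrenceTable):
        table = data
        if table.rule.get("rule", "distance") != "distance":
            raise ParameterError("Leibovici's entropy requires a distance-rule table")
    else:
        if d is None:
            raise ParameterError("distance d is required")
        table = distance_couples(data, d, symmetrise=symmetrise)
    return _couple_entropy(table, "leibovici")


def distance_sweep(data, d_list) -> "pd.DataFrame":
    """Relative Leibovici entropy across distances; empty tables are missing."""
    import pandas as pd

    rows = []
    for d in d_list:
        try:
            res = leibovici_entropy(data, d)
            rows.append({"d": float(d), "value": res.value,
                         "relative": res.relative,
                         "total_pairs": res.meta["total_pairs"]})
        except EmptyTableError:
            rows.append({"d": float(d), "value": np.nan, "relative": np.nan,
                         "total_pairs": 0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Distance summaries
# ---------------------------------------------------------------------------


@dataclass
class DistanceSummary:
    """Nearest-neighbour and all-pairs distances of a point pattern."""

    nn_distances: np.ndarray
    pairwise_distances: np.ndarray

    def nn_quantiles(self, q) -> np.ndarray:
        return np.quantile(self.nn_distances, q)

    def pairwise_quantiles(self, q) -> np.ndarray:
        return np.quantile(self.pairwise_distances, q)

    @property
    def median_pairwise(self) -> float:
        return float(np.median(self.pairwise_distances))


def distance_summaries(pattern: PointPattern) -> DistanceSummary:
    """Exact per-point nearest-neighbour and all-pairs distances."""
    if pattern.n < 2:
        raise ParameterError("distance summaries need at least two points")
    tree = cKDTree(pattern.coords)
    nn = tree.query(pattern.coords, k=2)[0][:, 1]
    pw = pdist(pattern.coords)
    return DistanceSummary(nn_distances=nn, pairwise_distances=pw)
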