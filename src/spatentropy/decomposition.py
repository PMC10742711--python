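"""Decomposable spatial entropy: H(Z) = MI(Z, W) + H(Z)_W.

Z is the unordered-pair variable over the I(I+1)/2 category pairs built
from *all* pairs of observations (no distance cutoff); W is a categorical
distance variable whose K classes (b_{k-1}, b_k] partition (0, inf).  The
Shannon entropy of Z splits exactly into spatial mutual information and a
spatial residual term:

    H(Z) = sum_k p(w_k) [ PI(Z|w_k) + H(Z|w_k) ]

where PI(Z|w_k) = sum_r p(z_r|w_k) ln[p(z_r|w_k) / p(z_r)] is a
Kullback-Leibler divergence (hence non-negative) and H(Z|w_k) is the
within-class Shannon entropy.  MI = sum_k p(w_k) PI(Z|w_k) measures the
diversity explained by distance; the residual measures all other sources of
heterogeneity.

Default distance classes: on square-cell grids the first class covers the 4
rook neighbours (distance c), the second the next 12 cells (distances up to
2c: diagonals c*sqrt(2) and axial 2c), the third is the residual class; on
point data, breaks at the deciles of the nearest-neighbour distance
distribution plus a residual class.  Duplicate breaks are deduplicated; a
pair at exactly a break belongs to the lower class; coincident observations
(distance 0) fall in the first class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import ParameterError
from .geometry import CategoricalRaster, PointPattern
from .shannon import entropy_nats

__all__ = [
    "DistanceClasses",
    "DecompositionResult",
    "default_breaks",
    "altieri_decomposition",
    "decomposition_profile",
    "pair_labels",
]


@dataclass(frozen=True)
class DistanceClasses:
    """K distance classes (b_{k-1}, b_k], b_0 = 0, b_K = inf."""

    finite_breaks: tuple[float, ...]  # ascending, strictly positive

    def __post_init__(self):
        breaks = tuple(float(b) for b in self.finite_breaks)
        if any(b <= 0 for b in breaks):
            raise ParameterError("distance breaks must be strictly positive")
        if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
            raise ParameterError("distance breaks must be strictly ascending")
        object.__setattr__(self, "finite_breaks", breaks)

    @property
    def K(self) -> int:
        return len(self.finite_breaks) + 1

    @property
    def labels(self) -> list[str]:
        edges = ["0"] + [f"{b:g}" for b in self.finite_breaks] + ["inf"]
        return [f"({lo}, {hi}]" for lo, hi in zip(edges, edges[1:])]

    def classify(self, distances: np.ndarray) -> np.ndarray:
        """Class index per distance; exact break -> lower class."""
        return np.searchsorted(np.asarray(self.finite_breaks),
                               np.asarray(distances), side="left")


def pair_labels(categories) -> list[str]:
    """The I(I+1)/2 unordered pair labels, lexicographic in category order."""
    cats = list(categories)
    return [f"{cats[i]}-{cats[j]}" for i in range(len(cats))
            for j in range(i, len(cats))]


def _pair_code_table(I: int) -> np.ndarray:
    """(I, I) lookup: code of the unordered pair {a, b}."""
    table = np.zeros((I, I), dtype=np.int64)
    code = 0
    for i in range(I):
        for j in range(i, I):
            table[i, j] = table[j, i] = code
            code += 1
    return table


def default_breaks(data) -> DistanceClasses:
    """The measure's default distance classes for a grid or point dataset."""
    if isinstance(data, CategoricalRaster):
        if not np.isclose(data.xstep, data.ystep):
            raise ParameterError(
                "no default distance classes for rectangular cells; "
                "supply breaks explicitly")
        c = float(data.xstep)
        return DistanceClasses((c, 2 * c))
    if isinstance(data, PointPattern):
        if data.n < 2:
            raise ParameterError("need at least two points for default breaks")
        tree = cKDTree(data.coords)
        nn = tree.query(data.coords, k=2)[0][:, 1]
        deciles = np.quantile(nn, np.arange(0.1, 0.91, 0.1))
        deciles = np.sort(deciles[deciles > 0])
        if deciles.size == 0:
            raise ParameterError("all nearest-neighbour distances are zero")
        # deduplicate to a relative tolerance (ties in the NN distribution)
        breaks = [float(deciles[0])]
        for b in deciles[1:]:
            if b > breaks[-1] * (1 + 1e-9):
                breaks.append(float(b))
        return DistanceClasses(tuple(breaks))
    raise ParameterError(f"unsupported data type {type(data).__name__}")


@dataclass
class DecompositionResult:
    """Global and per-distance-class terms of the entropy decomposition."""

    categories: list
    pair_names: list[str]
    classes: DistanceClasses
    class_labels: list[str]  # non-empty classes only
    class_weights: np.ndarray  # p(w_k)
    class_counts: np.ndarray  # (K_nonempty, R) pair counts per class
    global_counts: np.ndarray  # (R,) pair counts
    H_Z: float
    MI: float
    residual: float
    PI_terms: np.ndarray  # PI(Z|w_k)
    H_terms: np.ndarray  # H(Z|w_k)

    def to_dict(self) -> dict:
        total = self.global_counts.sum()
        return {
            "measure": "altieri_decomposition",
            "H_Z": float(self.H_Z),
            "MI": float(self.MI),
            "residual": float(self.residual),
            "pair_table": [
                {"pair": nm, "count": float(c), "prob": float(c / total)}
                for nm, c in zip(self.pair_names, self.global_counts)],
            "classes": [
                {"class": lab, "weight": float(w), "PI": float(pi),
                 "H": float(hh),
                 "pairs": [{"pair": nm, "count": float(c)}
                           for nm, c in zip(self.pair_names, row)]}
                for lab, w, pi, hh, row in zip(
                    self.class_labels, self.class_weights, self.PI_terms,
                    self.H_terms, self.class_counts)],
        }


def _all_pair_class_counts(coords: np.ndarray, codes: np.ndarray, I: int,
                           classes: DistanceClasses,
                           block: int = 512) -> np.ndarray:
    """(K, R) counts over all unordered observation pairs, blockwise O(n^2)."""
    n = len(coords)
    pc = _pair_code_table(I)
    R = I * (I + 1) // 2
    K = classes.K
    out = np.zeros(K * R, dtype=np.int64)
    breaks = np.asarray(classes.finite_breaks)
    for i0 in range(0, n - 1, block):
        i1 = min(i0 + block, n - 1)
        D = cdist(coords[i0:i1], coords[i0:])
        rows, cols = np.triu_indices(i1 - i0, 1, D.shape[1])
        d = D[rows, cols]
        cls = np.searchsorted(breaks, d, side="left")
        pair = pc[codes[i0 + rows], codes[i0 + cols]]
        out += np.bincount(cls * R + pair, minlength=K * R)
    return out.reshape(K, R)


def altieri_decomposition(data, classes: DistanceClasses | None = None
                          ) -> DecompositionResult:
    """Decompose the unordered-pair entropy into spatial MI and residual.

    All unordered pairs of observations are enumerated (no cutoff) and
    cross-classified by category pair and distance class.  Empty distance
    classes are dropped with a warning (their weight is zero).
    """
    if isinstance(data, PointPattern):
        if data.marks is None:
            raise ParameterError("decomposable entropy on points requires marks")
        coords, values = data.coords, data.marks
    elif isinstance(data, CategoricalRaster):
        coords, values = data.valid_centroids(), data.valid_values()
    else:
        raise ParameterError(f"unsupported data type {type(data).__name__}")
    if len(coords) < 2:
        raise ParameterError("need at least two observations")
    if classes is None:
        classes = default_breaks(data)

    seen: dict = {}
    for v in values:
        seen.setdefault(v, None)
    cats = list(seen)
    lookup = {c: i for i, c in enumerate(cats)}
    codes = np.array([lookup[v] for v in values], dtype=np.int64)
    I = len(cats)

    counts = _all_pair_class_counts(np.asarray(coords, float), codes, I, classes)
    names = pair_labels(cats)
    labels = classes.labels
    keep = counts.sum(axis=1) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} empty distance class(es)",
                      stacklevel=2)
    counts = counts[keep]
    labels = [lab for lab, k in zip(labels, keep) if k]

    total = counts.sum()
    global_counts = counts.sum(axis=0)
    pz = global_counts / total
    weights = counts.sum(axis=1) / total

    PI = np.empty(len(counts))
    H = np.empty(len(counts))
    for k, row in enumerate(counts):
        pk = row / row.sum()
        pos = pk > 0
        PI[k] = float((pk[pos] * np.log(pk[pos] / pz[pos])).sum())
        H[k] = entropy_nats(pk)
    MI = float((weights * PI).sum())
    residual = float((weights * H).sum())
    return DecompositionResult(
        categories=cats, pair_names=names, classes=classes,
        class_labels=labels, class_weights=weights, class_counts=counts,
        global_counts=global_counts, H_Z=entropy_nats(pz), MI=MI,
        residual=residual, PI_terms=PI, H_terms=H)


def decomposition_profile(result: DecompositionResult) -> "pd.DataFrame":
    """Per-class spatial vs residual shares, for the decomposition bar plot.

    Each class contributes PI / (PI + H) (spatial share) and H / (PI + H)
    (residual share), defined as (0, 1) when both terms vanish.
    """
    import pandas as pd

    rows = []
    for lab, w, pi, hh in zip(result.class_labels, result.class_weights,
                              result.PI_terms, result.H_terms):
        tot = pi + hh
        spatial = pi / tot if tot > 0 else 0.0
        rows.append({"class": lab, "weight": float(w),
                     "PI": float(pi), "H": float(hh),
                     "spatial_share": float(spatial),
                     "residual_share": float(1.0 - spatial)})
    return pd.DataFrame(rows)
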