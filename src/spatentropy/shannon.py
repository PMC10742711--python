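"""Shannon's entropy on category frequencies.

H(X) = sum_i p(x_i) ln(1/p(x_i)), with plug-in probabilities (relative
frequencies n_i/n) and the continuity convention 0 * ln(1/0) = 0.  Values
are in nats; the relative entropy is H / ln(I) for I observed categories
(defined as 1 when I = 1, where the range degenerates to [0, 0]).

Shannon's entropy is spatially invariant: it reads only the multiset of
category values, so rearranging points or raster cells leaves it unchanged.
The partition-based and co-occurrence-based measures in the sibling modules
exist precisely to remedy this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .geometry import CategoricalRaster, PointPattern
from .results import EntropyResult

__all__ = ["CategoryDistribution", "tabulate", "shannon_entropy", "entropy_nats"]


@dataclass
class CategoryDistribution:
    """Counts and relative frequencies per category label."""

    labels: list
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if len(self.labels) != len(self.counts):
            raise ParameterError("labels and counts differ in length")
        if len(self.labels) < 1:
            raise ParameterError("need at least one category")
        if (self.counts < 0).any():
            raise ParameterError("counts must be non-negative")

    @classmethod
    def from_counts(cls, labels, counts) -> "CategoryDistribution":
        return cls(list(labels), np.asarray(counts))

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @property
    def probs(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ParameterError("empty distribution has no probabilities")
        return self.counts / total

    @property
    def I(self) -> int:  # noqa: E743 - standard symbol for category count
        return len(self.labels)

    def to_records(self) -> list[dict]:
        p = self.probs
        return [{"label": str(lab), "count": float(c), "prob": float(pi)}
                for lab, c, pi in zip(self.labels, self.counts, p)]


def tabulate(source) -> CategoryDistribution:
    """Category counts from point marks or valid raster cells.

    Label order is first appearance (stable).
    """
    if isinstance(source, PointPattern):
        if source.marks is None:
            raise ParameterError("point pattern has no marks to tabulate")
        values = source.marks
    elif isinstance(source, CategoricalRaster):
        values = source.valid_values()
    else:
        values = np.asarray(source, dtype=object).reshape(-1)
    if len(values) == 0:
        raise ParameterError("cannot tabulate an empty source")
    order: dict = {}
    for v in values:
        order[v] = order.get(v, 0) + 1
    return CategoryDistribution(list(order), np.array(list(order.values())))


def entropy_nats(probs: np.ndarray) -> float:
    """Plug-in Shannon entropy of a probability vector, zero terms dropped."""
    p = np.asarray(probs, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def shannon_entropy(dist) -> EntropyResult:
    """Shannon's entropy of a category distribution (or pattern/raster).

    Returns the value in nats, the range [0, ln I], and the relative
    entropy H / ln I.
    """
    if not isinstance(dist, CategoryDistribution):
        dist = tabulate(dist)
    if dist.n <= 0:
        raise ParameterError("Shannon entropy needs at least one observation")
    h = entropy_nats(dist.probs)
    hmax = float(np.log(dist.I))
    relative = h / hmax if hmax > 0 else 1.0
    return EntropyResult(measure="shannon", value=h, range_min=0.0,
                         range_max=hmax, relative=relative, table=dist,
                         meta={"I": dist.I, "n": dist.n})
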