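"""Seeded synthetic data generators and the two sensitivity studies.

Generators emulate the features of field data the entropy measures respond
to: complete spatial randomness (the null model), Thomas-type clustering
(parents with Gaussian-displaced offspring, marks optionally inherited from
the parent so that short-range pairs share categories), and spatially
autocorrelated binary rasters (thresholded smoothed noise).  Every generator
is a pure function of its configuration and seed; PCG64 streams are derived
per call from the given seed via NumPy's SeedSequence, so fixtures are
stable across runs.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .cooccurrence import (
    contagion,
    contiguous_couples,
    leibovici_entropy,
    oneill_entropy,
    parresol_edwards,
)
from .errors import ParameterError
from .geometry import (
    CategoricalRaster,
    ObservationWindow,
    PointPattern,
    pixellate,
    sample_points_in_polygon,
)
from .shannon import shannon_entropy, tabulate

__all__ = [
    "generate_csr",
    "generate_clustered",
    "generate_autocorrelated_raster",
    "resolution_sensitivity",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_csr(window: ObservationWindow, n: int, seed,
                 mark_probs: dict | None = None) -> PointPattern:
    """n uniform points in the window (complete spatial randomness).

    With ``mark_probs`` ({label: probability}) marks are drawn independently
    of location — the random-labelling null for the co-occurrence measures.
    """
    if n < 0:
        raise ParameterError("n must be >= 0")
    rng = _rng(seed)
    coords = (sample_points_in_polygon(window, n, rng) if n
              else np.empty((0, 2)))
    marks = None
    if mark_probs is not None:
        labels = list(mark_probs)
        probs = np.array([mark_probs[k] for k in labels], float)
        if not np.isclose(probs.sum(), 1.0) or (probs < 0).any():
            raise ParameterError("mark probabilities must be >= 0 and sum to 1")
        marks = rng.choice(np.array(labels, dtype=object), size=n, p=probs)
    return PointPattern(coords, window, marks)


def generate_clustered(window: ObservationWindow, parents: int,
                       offspring_mean: float, spread: float, seed,
                       mark_probs: dict | None = None,
                       inherit_marks: bool = False) -> PointPattern:
    """Thomas-type cluster process: uniform parents, Gaussian offspring.

    Each parent receives Poisson(offspring_mean) offspring displaced by an
    isotropic Gaussian with standard deviation ``spread``; offspring falling
    outside the window are discarded.  Marks are drawn per point
    (independent labelling) or per parent and inherited by its offspring,
    which plants genuine short-range category association.
    """
    if parents < 0 or offspring_mean < 0 or spread < 0:
        raise ParameterError("parents, offspring_mean and spread must be >= 0")
    rng = _rng(seed)
    parent_xy = (sample_points_in_polygon(window, parents, rng) if parents
                 else np.empty((0, 2)))
    labels = probs = None
    if mark_probs is not None:
        labels = np.array(list(mark_probs), dtype=object)
        probs = np.array([mark_probs[k] for k in labels], float)
        if not np.isclose(probs.sum(), 1.0) or (probs < 0).any():
            raise ParameterError("mark probabilities must be >= 0 and sum to 1")
    pts: list[np.ndarray] = []
    marks: list = []
    for p_xy in parent_xy:
        k = rng.poisson(offspring_mean)
        parent_mark = (rng.choice(labels, p=probs)
                       if labels is not None and inherit_marks else None)
        if k == 0:
            continue
        off = p_xy + rng.normal(scale=spread, size=(k, 2))
        inside = (np.ones(k, bool) if spread == 0
                  else window.covers(off[:, 0], off[:, 1]))
        for xy in off[inside]:
            pts.append(xy)
            if labels is not None:
                marks.append(parent_mark if inherit_marks
                             else rng.choice(labels, p=probs))
    coords = np.array(pts).reshape(-1, 2)
    mk = np.array(marks, dtype=object) if mark_probs is not None else None
    return PointPattern(coords, window, mk)


def generate_autocorrelated_raster(nrows: int, ncols: int, p1: float,
                                   smoothing: float, seed,
                                   origin=(0.0, 0.0), xstep: float = 1.0,
                                   ystep: float = 1.0) -> CategoricalRaster:
    """Binary raster from thresholded smoothed Gaussian noise.

    The noise field is smoothed with a Gaussian kernel of standard deviation
    ``smoothing`` (in cells; 0 means i.i.d. cells) and thresholded at the
    empirical (1 - p1) quantile, giving marginal presence frequency close to
    p1 and spatial clumping that grows with the smoothing radius.
    """
    if not 0 <= p1 <= 1:
        raise ParameterError("p1 must be in [0, 1]")
    if smoothing < 0:
        raise ParameterError("smoothing must be >= 0")
    rng = _rng(seed)
    field = rng.standard_normal((nrows, ncols))
    if smoothing > 0:
        field = ndimage.gaussian_filter(field, sigma=smoothing)
    if p1 <= 0:
        values = np.zeros((nrows, ncols), int)
    elif p1 >= 1:
        values = np.ones((nrows, ncols), int)
    else:
        thr = np.quantile(field, 1.0 - p1)
        values = (field > thr).astype(int)
    return CategoricalRaster(values, np.zeros((nrows, ncols), bool),
                             origin=origin, xstep=xstep, ystep=ystep)


_KNOWN_MEASURES = ("shannon", "oneill", "contagion", "parredw", "leibovici")


def resolution_sensitivity(pattern: PointPattern, resolutions,
                           measures=("shannon",),
                           distances=None) -> "pd.DataFrame":
    """Grid-resolution sensitivity of the pixellation-based measures.

    For each resolution r the pattern is pixellated to an r x r (or
    (nrows, ncols)) binary presence grid and the requested measures are
    computed on it.  ``distances`` gives the fixed physical distances for
    the Leibovici columns.  Rows report the occupied-cell count, the
    occupied fraction of valid cells, and each measure's relative value.
    """
    import pandas as pd

    for m in measures:
        if m not in _KNOWN_MEASURES:
            raise ParameterError(f"unknown measure {m!r}; choose from "
                                 f"{_KNOWN_MEASURES}")
    if "leibovici" in measures and not distances:
        raise ParameterError("the leibovici measure needs 'distances'")
    rows = []
    for res in resolutions:
        nrows, ncols = (res, res) if np.isscalar(res) else res
        rast = pixellate(pattern, nrows, ncols)
        occupied = int((rast.values[~rast.mask] == 1).sum())
        row = {"nrows": nrows, "ncols": ncols,
               "occupied_cells": occupied,
               "occupied_fraction": occupied / rast.n_valid}
        binary = len(rast.categories()) > 1
        for m in measures:
            if m == "shannon":
                row["shannon_rel"] = (shannon_entropy(tabulate(rast)).relative
                                      if binary else 0.0)
            elif m in {"oneill", "contagion", "parredw"}:
                table = contiguous_couples(rast)
                fn = {"oneill": oneill_entropy, "contagion": contagion,
                      "parredw": parresol_edwards}[m]
                res_ = fn(table)
                row[f"{m}_rel"] = (res_.relative if binary
                                   else (1.0 if m == "contagion" else 0.0))
            elif m == "leibovici":
                for d in distances:
                    rel = (leibovici_entropy(rast, d).relative if binary
                           else 0.0)
                    row[f"leibovici_rel_d{d:g}"] = rel
        rows.append(row)
    return pd.DataFrame(rows)
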