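"""Free-energy surfaces: the well-tempered estimator, umbrella-sampling-like
reweighting, block-analysis errors, and basin identification.

From a converged WT-MetaD bias the free energy along the biased CV is

    F(s) = -(gamma / (gamma - 1)) * V(s),

shifted so its minimum is zero.  Unbiased distributions along *any* CV are
recovered by weighting each frame with exp(+V(s_f)/k_B T) (the final-bias
approximation of the umbrella-sampling-like reweighting) and reading
F = -k_B T log(histogram).  Statistical errors come from block analysis of
the weighted histogram: for correlated series the block error grows with the
block size until it plateaus at the true uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .constants import KB_KCAL_MOL_K
from .errors import ComputationError, ValidationError
from .metad import HillsLog, bias_potential
from .trajio import write_plumed_table

__all__ = [
    "FES",
    "Basin",
    "fes_from_hills",
    "reweight",
    "reweight_weights",
    "block_error",
    "find_basins",
]


@dataclass
class FES:
    """Free energy on a 1-D or 2-D CV grid, min-shifted to zero."""

    centers: tuple[np.ndarray, ...]
    values: np.ndarray
    error: np.ndarray | None = None
    gamma: float | None = None

    def __post_init__(self) -> None:
        self.centers = tuple(np.asarray(c, dtype=float) for c in self.centers)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != len(self.centers):
            raise ValidationError("grid axes do not match value dimensionality")
        finite = np.isfinite(self.values)
        if not finite.any():
            raise ValidationError("FES has no finite values")
        self.values = self.values - self.values[finite].min()
        if self.error is not None:
            self.error = np.asarray(self.error, dtype=float)
            if self.error.shape != self.values.shape:
                raise ValidationError("error grid shape mismatch")
            if np.any(self.error[np.isfinite(self.error)] < 0):
                raise ValidationError("errors must be non-negative")

    @property
    def ndim(self) -> int:
        return self.values.ndim

    def write(self, path: str | Path) -> None:
        """Whitespace grid text (sum_hills-style layout)."""
        if self.ndim == 1:
            data = np.column_stack([self.centers[0], self.values])
            write_plumed_table(path, ["s", "free_energy"], data)
        else:
            xx, yy = np.meshgrid(self.centers[0], self.centers[1], indexing="ij")
            data = np.column_stack([xx.ravel(), yy.ravel(), self.values.ravel()])
            write_plumed_table(path, ["s0", "s1", "free_energy"], data)


@dataclass
class Basin:
    """One free-energy basin."""

    label: str
    location: tuple[float, ...]
    depth: float          # dF of the basin minimum above the global minimum
    persistence: float    # depth below the basin's lowest exit saddle
    member_nodes: list[tuple[int, ...]] = field(default_factory=list)


def fes_from_hills(
    hills: HillsLog | Sequence,
    grid: np.ndarray | tuple[float, float, int],
    gamma: float,
) -> FES:
    """Well-tempered FES estimate F(s) = -(gamma/(gamma-1)) V(s), min 0."""
    if gamma <= 1:
        raise ValidationError("bias factor must exceed 1")
    n_hills = len(hills) if not isinstance(hills, HillsLog) else len(hills)
    if n_hills == 0:
        raise ValidationError("empty hills log")
    x = (np.asarray(grid, dtype=float) if not isinstance(grid, tuple)
         else np.linspace(*grid))
    v = np.asarray(bias_potential(x, hills), dtype=float)
    f = -(gamma / (gamma - 1.0)) * v
    return FES(centers=(x,), values=f, gamma=gamma)


def reweight_weights(
    cv_series: np.ndarray,
    bias,
    temperature: float,
) -> np.ndarray:
    """Normalised frame weights w_f ~ exp(+V(s_f)/k_B T).

    ``bias`` is a per-frame array of bias energies, a callable ``s -> V``,
    or a :class:`HillsLog` (final-bias approximation).
    """
    s = np.asarray(cv_series, dtype=float)
    first_axis = s if s.ndim == 1 else s[:, 0]
    if isinstance(bias, HillsLog):
        v = np.asarray(bias.potential(first_axis), dtype=float)
    elif callable(bias):
        v = np.asarray([bias(x) for x in first_axis], dtype=float)
    else:
        v = np.asarray(bias, dtype=float)
        if v.shape[0] != s.shape[0]:
            raise ValidationError("one bias energy per frame is required")
    kbt = KB_KCAL_MOL_K * temperature
    logw = v / kbt
    logw -= logw.max()
    w = np.exp(logw)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ComputationError("all reweighting weights vanished")
    return w / total


def reweight(
    cv_series: np.ndarray,
    bias,
    temperature: float,
    bins: int | Sequence[int] = 100,
    range_: tuple | None = None,
) -> FES:
    """Unbiased FES on arbitrary CVs from a biased trajectory.

    ``cv_series`` is (n,) for 1-D or (n, 2) for 2-D output CVs; ``bias``
    supplies V at each frame (see :func:`reweight_weights` — for a zero/None
    bias this is the identity estimator, i.e. the plain histogram estimate).
    Empty bins carry +inf free energy.
    """
    s = np.asarray(cv_series, dtype=float)
    if bias is None:
        bias = np.zeros(s.shape[0])
    w = reweight_weights(s, bias, temperature)
    kbt = KB_KCAL_MOL_K * temperature
    if s.ndim == 1 or s.shape[1] == 1:
        flat = s.ravel() if s.ndim == 1 else s[:, 0]
        hist, edges = np.histogram(flat, bins=bins, range=range_, weights=w,
                                   density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        with np.errstate(divide="ignore"):
            f = -kbt * np.log(hist)
        return FES(centers=(centers,), values=f)
    if s.shape[1] != 2:
        raise ValidationError("reweight supports 1-D or 2-D output CVs")
    hist, ex, ey = np.histogram2d(s[:, 0], s[:, 1], bins=bins, range=range_,
                                  weights=w, density=True)
    cx = 0.5 * (ex[:-1] + ex[1:])
    cy = 0.5 * (ey[:-1] + ey[1:])
    with np.errstate(divide="ignore"):
        f = -kbt * np.log(hist)
    return FES(centers=(cx, cy), values=f)


def block_error(
    cv_series: np.ndarray,
    weights: np.ndarray | None,
    temperature: float,
    bins: int = 50,
    range_: tuple[float, float] | None = None,
    block_sizes: Sequence[int] | None = None,
    plateau_rtol: float = 0.05,
) -> tuple[pd.DataFrame, tuple[int, float]]:
    """Block-analysis error of the (weighted) free-energy histogram.

    For each block size the series is cut into contiguous blocks and the
    weighted histogram is averaged block-wise; the free-energy error per node
    is the standard error of the block probabilities propagated through
    F = -k_B T log p (i.e. k_B T * SE(p)/p).  The reported error is the
    average over populated nodes.  Returns (curve DataFrame with columns
    block_size/error, (plateau_size, plateau_error)); the plateau is the
    first size whose successor changes by less than ``plateau_rtol``.
    """
    s = np.asarray(cv_series, dtype=float).ravel()
    n = s.size
    w = (np.ones(n) if weights is None else np.asarray(weights, dtype=float))
    if w.shape != s.shape:
        raise ValidationError("weights must match the series length")
    if block_sizes is None:
        sizes, b = [], max(10, n // 2048)
        while n // b >= 2:
            sizes.append(b)
            b *= 2
        block_sizes = sizes
    block_sizes = [int(b) for b in block_sizes]
    if not block_sizes or n // max(block_sizes) < 2:
        raise ValidationError("series too short for the requested block sizes")
    kbt = KB_KCAL_MOL_K * temperature
    if range_ is None:
        range_ = (float(s.min()), float(s.max()))
    edges = np.linspace(range_[0], range_[1], bins + 1)

    rows = []
    for b in block_sizes:
        nb = n // b
        # per-block weighted probability vectors (block weights normalised
        # by the block's own total weight, blocks weighted equally)
        probs = np.empty((nb, bins))
        for i in range(nb):
            sl = slice(i * b, (i + 1) * b)
            hist, _ = np.histogram(s[sl], bins=edges, weights=w[sl])
            tot = hist.sum()
            if tot <= 0:
                raise ComputationError(f"block {i} of size {b} has zero weight")
            probs[i] = hist / tot
        p_mean = probs.mean(axis=0)
        ok = p_mean > 0
        if not ok.any():
            raise ComputationError("no histogram node populated")
        se_p = probs[:, ok].std(axis=0, ddof=1) / np.sqrt(nb)
        err_f = kbt * se_p / p_mean[ok]
        rows.append({"block_size": b, "n_blocks": nb,
                     "error": float(err_f.mean())})
    curve = pd.DataFrame(rows)
    errs = curve["error"].to_numpy()
    plateau_idx = len(errs) - 1
    for i in range(len(errs) - 1):
        if abs(errs[i + 1] - errs[i]) < plateau_rtol * max(errs[i], 1e-300):
            plateau_idx = i
            break
    return curve, (int(curve["block_size"][plateau_idx]),
                   float(errs[plateau_idx]))


def _neighbors(shape: tuple[int, ...], idx: tuple[int, ...]):
    for axis in range(len(shape)):
        for step in (-1, 1):
            j = idx[axis] + step
            if 0 <= j < shape[axis]:
                yield idx[:axis] + (j,) + idx[axis + 1:]


def find_basins(fes: FES, min_depth: float = 0.5) -> list[Basin]:
    """Persistence-based basin detection.

    Nodes are flooded in order of increasing free energy; a basin is born at
    each local minimum and dies where it first meets a deeper basin (its
    lowest exit saddle).  Basins whose persistence (saddle minus minimum) is
    at least ``min_depth`` are kept, sorted by depth above the global
    minimum, global minimum first.
    """
    vals = fes.values
    shape = vals.shape
    order = np.argsort(vals, axis=None, kind="stable")
    parent: dict[tuple[int, ...], tuple[int, ...]] = {}
    comp_min: dict[tuple[int, ...], tuple[float, tuple[int, ...]]] = {}
    members: dict[tuple[int, ...], list[tuple[int, ...]]] = {}
    basins: list[Basin] = []

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def location_of(idx: tuple[int, ...]) -> tuple[float, ...]:
        return tuple(float(fes.centers[a][idx[a]]) for a in range(len(idx)))

    for flat in order:
        idx = np.unravel_index(flat, shape)
        level = vals[idx]
        if not np.isfinite(level):
            continue
        parent[idx] = idx
        comp_min[idx] = (float(level), idx)
        members[idx] = [idx]
        for nb in _neighbors(shape, idx):
            if nb not in parent:
                continue
            ra, rb = find(idx), find(nb)
            if ra == rb:
                continue
            (min_a, arg_a), (min_b, arg_b) = comp_min[ra], comp_min[rb]
            # the shallower (younger) component dies at this saddle
            if min_a > min_b:
                young, old = ra, rb
                young_min, young_arg = min_a, arg_a
            else:
                young, old = rb, ra
                young_min, young_arg = min_b, arg_b
            persistence = float(level) - young_min
            if persistence >= min_depth:
                basins.append(Basin(
                    label="", location=location_of(young_arg),
                    depth=young_min, persistence=persistence,
                    member_nodes=list(members[young]),
                ))
            parent[young] = old
            members[old].extend(members.pop(young))
            comp_min[old] = min(comp_min[old], comp_min.pop(young))
    # surviving root components are basins with unbounded persistence
    roots = {find(x) for x in parent}
    for r in roots:
        mn, arg = comp_min[r]
        basins.append(Basin(label="", location=location_of(arg), depth=mn,
                            persistence=float("inf"),
                            member_nodes=list(members[r])))
    basins.sort(key=lambda b: b.depth)
    for i, b in enumerate(basins):
        b.label = f"B{i}" if i else "global"
    return basins
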