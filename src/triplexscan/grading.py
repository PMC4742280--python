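"""Two-dimensional score/energy dominance ranking and percentile grades.

Within one scan run (one genome x miRNA set), each reported site is ranked
by the number of other sites with a strictly *better* score/energy
combination: strictly higher score AND strictly lower (more favorable)
energy.  Pareto-incomparable sites do not dominate each other; ties in
either dimension do not dominate.

Grades 1-5 are nested percentile classes of this dominance count: a site is
grade g when its dominance count is within the top ``cutoff_g`` fraction of
the graded population (defaults 1e-5, 1e-4, 1e-3, 1e-2, 1e-1, i.e. the
99.999th down to the 90th percentile).  Only the first four cut-offs follow
the stated ten-fold pattern explicitly; the fifth continues it and is
configurable.

For arbitrary (score, energy) queries a dominance-count surface is tabulated
on a grid and interpolated bilinearly.  By default the grid nodes are the
exact observed score/energy values (capped; coarser regular bins beyond the
cap), so grid points reproduce the discrete grades exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .scan import TriplexSite

logger = logging.getLogger(__name__)

#: grade -> fraction of the graded population allowed at or above this grade
DEFAULT_CUTOFFS: Dict[int, float] = {1: 1e-5, 2: 1e-4, 3: 1e-3, 4: 1e-2, 5: 1e-1}

_DEFAULT_SCORE_BIN = 20.0  # native heuristic-score step
_DEFAULT_ENERGY_BIN = 0.5  # kcal/mol
_MAX_EXACT_NODES = 1024


class _Fenwick:
    """Binary indexed tree over 1..n for prefix counts."""

    def __init__(self, n: int):
        self.n = n
        self.tree = np.zeros(n + 1, dtype=np.int64)

    def add(self, i: int) -> None:  # 1-based
        while i <= self.n:
            self.tree[i] += 1
            i += i & (-i)

    def prefix(self, i: int) -> int:  # count of inserted indices <= i
        s = 0
        while i > 0:
            s += self.tree[i]
            i -= i & (-i)
        return int(s)


def dominance_rank(
    scores: Sequence[float], energies: Sequence[float]
) -> np.ndarray:
    """Per-site count of sites with strictly higher score and lower energy.

    Sort-plus-order-statistic sweep, O(n log n): process sites in descending
    score order, holding out ties, and query how many already-inserted sites
    (strictly higher score) have strictly lower energy.
    """
    scores = np.asarray(scores, dtype=float)
    energies = np.asarray(energies, dtype=float)
    n = scores.size
    if n == 0:
        raise ValueError("dominance_rank needs at least one site")
    if energies.size != n:
        raise ValueError("scores and energies must have equal length")
    counts = np.zeros(n, dtype=np.int64)
    # compress energies to ranks 1..m
    uniq = np.unique(energies)
    erank = np.searchsorted(uniq, energies) + 1
    order = np.argsort(-scores, kind="stable")
    bit = _Fenwick(uniq.size)
    i = 0
    while i < n:
        j = i
        while j < n and scores[order[j]] == scores[order[i]]:
            j += 1
        for t in range(i, j):  # query before inserting the tie group
            idx = order[t]
            counts[idx] = bit.prefix(int(erank[idx]) - 1)
        for t in range(i, j):
            bit.add(int(erank[order[t]]))
        i = j
    return counts


def _grade_from_count(count: float, n_total: int, cutoffs: Dict[int, float]) -> int:
    for g in sorted(cutoffs):
        if count <= cutoffs[g] * n_total:
            return g
    return 0


@dataclass
class GradeModel:
    """Empirical dominance distribution of one scan run, plus query grid."""

    n_total: int
    scores: np.ndarray
    energies: np.ndarray
    dominance_counts: np.ndarray
    grade_cutoffs: Dict[int, float] = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))
    score_grid: np.ndarray = field(default_factory=lambda: np.array([]))
    energy_grid: np.ndarray = field(default_factory=lambda: np.array([]))
    count_grid: np.ndarray = field(default_factory=lambda: np.array([[]]))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#n_total\t{self.n_total}\n")
            cut = ",".join(f"{g}:{c!r}" for g, c in sorted(self.grade_cutoffs.items()))
            fh.write(f"#cutoffs\t{cut}\n")
            fh.write("#score_grid\t" + ",".join(repr(float(s)) for s in self.score_grid) + "\n")
            fh.write("#energy_grid\t" + ",".join(repr(float(e)) for e in self.energy_grid) + "\n")
            for row in self.count_grid:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def from_file(cls, path) -> "GradeModel":
        meta: Dict[str, str] = {}
        rows: List[List[float]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line[1:].partition("\t")
                    meta[key] = val
                else:
                    rows.append([float(v) for v in line.split("\t")])
        cutoffs = {}
        for part in meta["cutoffs"].split(","):
            g, _, c = part.partition(":")
            cutoffs[int(g)] = float(c)
        sg = np.array([float(v) for v in meta["score_grid"].split(",") if v])
        eg = np.array([float(v) for v in meta["energy_grid"].split(",") if v])
        return cls(
            n_total=int(meta["n_total"]),
            scores=np.array([]),
            energies=np.array([]),
            dominance_counts=np.array([]),
            grade_cutoffs=cutoffs,
            score_grid=sg,
            energy_grid=eg,
            count_grid=np.array(rows),
        )


def _grid_axis(values: np.ndarray, bin_width: float) -> np.ndarray:
    uniq = np.unique(values)
    if uniq.size <= _MAX_EXACT_NODES:
        return uniq
    lo = np.floor(uniq.min() / bin_width) * bin_width
    hi = np.ceil(uniq.max() / bin_width) * bin_width
    n_bins = int(round((hi - lo) / bin_width)) + 1
    if n_bins <= _MAX_EXACT_NODES:
        return lo + bin_width * np.arange(n_bins)
    # very wide ranges: fall back to a uniform grid at the node cap
    return np.linspace(lo, hi, _MAX_EXACT_NODES)


def fit_grade_model(
    scores: Sequence[float],
    energies: Sequence[float],
    cutoffs: Optional[Dict[int, float]] = None,
    score_bin: float = _DEFAULT_SCORE_BIN,
    energy_bin: float = _DEFAULT_ENERGY_BIN,
) -> GradeModel:
    """Rank a scan run's (score, energy) pairs and tabulate the query grid."""
    scores = np.asarray(scores, dtype=float)
    energies = np.asarray(energies, dtype=float)
    if cutoffs is None:
        cutoffs = dict(DEFAULT_CUTOFFS)
    got = sorted(cutoffs.items())
    if any(b[1] <= a[1] for a, b in zip(got, got[1:])):
        raise ValueError("grade cut-offs must be strictly increasing")
    counts = dominance_rank(scores, energies)
    score_grid = _grid_axis(scores, score_bin)
    energy_grid = _grid_axis(energies, energy_bin)
    # count_grid[a, b] = number of sites with score > S_a and energy < E_b
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_energies = energies[order]
    count_grid = np.zeros((score_grid.size, energy_grid.size))
    for a in range(score_grid.size - 1, -1, -1):
        m = np.searchsorted(-sorted_scores, -score_grid[a], side="left")
        e_gt = np.sort(sorted_energies[:m])
        count_grid[a, :] = np.searchsorted(e_gt, energy_grid, side="left")
    return GradeModel(
        n_total=int(scores.size),
        scores=scores,
        energies=energies,
        dominance_counts=counts,
        grade_cutoffs=cutoffs,
        score_grid=score_grid,
        energy_grid=energy_grid,
        count_grid=count_grid,
    )


def assign_grades(model: GradeModel) -> np.ndarray:
    """Grade 1-5 per graded site; 0 when outside the last cut-off."""
    return np.array(
        [
            _grade_from_count(c, model.n_total, model.grade_cutoffs)
            for c in model.dominance_counts
        ],
        dtype=int,
    )


def interpolate_dominance(
    score: float, energy: float, model: GradeModel
) -> Tuple[float, bool]:
    """Bilinear dominance count at an arbitrary (score, energy) query.

    Queries outside the grid's convex hull are clamped to the nearest
    boundary cell; the returned flag reports whether clamping happened.
    """
    sg, eg, grid = model.score_grid, model.energy_grid, model.count_grid
    clamped = not (sg[0] <= score <= sg[-1]) or not (eg[0] <= energy <= eg[-1])
    s = float(np.clip(score, sg[0], sg[-1]))
    e = float(np.clip(energy, eg[0], eg[-1]))

    def _locate(axis: np.ndarray, v: float) -> Tuple[int, float]:
        if axis.size == 1:
            return 0, 0.0
        i = int(np.searchsorted(axis, v, side="right") - 1)
        i = min(max(i, 0), axis.size - 2)
        frac = (v - axis[i]) / (axis[i + 1] - axis[i])
        return i, float(frac)

    ia, fa = _locate(sg, s)
    ib, fb = _locate(eg, e)
    if sg.size == 1 and eg.size == 1:
        val = grid[0, 0]
    elif sg.size == 1:
        val = (1 - fb) * grid[0, ib] + fb * grid[0, ib + 1]
    elif eg.size == 1:
        val = (1 - fa) * grid[ia, 0] + fa * grid[ia + 1, 0]
    else:
        val = (
            (1 - fa) * (1 - fb) * grid[ia, ib]
            + fa * (1 - fb) * grid[ia + 1, ib]
            + (1 - fa) * fb * grid[ia, ib + 1]
            + fa * fb * grid[ia + 1, ib + 1]
        )
    if clamped:
        logger.warning(
            "grade query (%.6g, %.6g) outside the fitted grid; clamped", score, energy
        )
    return float(val), clamped


def interpolate_grade(score: float, energy: float, model: GradeModel) -> int:
    """Grade for an arbitrary (score, energy) pair via the fitted surface."""
    count, _ = interpolate_dominance(score, energy, model)
    return _grade_from_count(count, model.n_total, model.grade_cutoffs)


def grade_sites(
    sites: List[TriplexSite], cutoffs: Optional[Dict[int, float]] = None
) -> GradeModel:
    """Fit a model on a site list and write grades back onto the sites."""
    if not sites:
        raise ValueError("no sites to grade")
    model = fit_grade_model(
        [s.score for s in sites], [s.energy for s in sites], cutoffs
    )
    for site, g in zip(sites, assign_grades(model)):
        site.grade = int(g)
    return model
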