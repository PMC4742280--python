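"""Synthetic inputs with known ground truth.

Two generators: uniform-background genomes with triplex targets planted at
known coordinates (to test recovery by the scanner), and paired expression
cohorts with planted rank correlations via a Gaussian copula (to test the
correlation meta-analysis and the enrichment statistic).  All randomness is
behind one seeded generator per call, so every fixture is reproducible.

What these emulate and what they do not: planted genomes have uniform base
composition (no isochores, repeats or CpG structure), and cohorts have
normal margins with exact rank-preserving dependence (no microarray noise
physics, batch effects or missingness).  Passing recovery tests therefore
demonstrates correctness of the machinery, not performance on real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .enrichment import ExpressionCohort
from .pairing import BindingMode, Orientation, count_favorable
from .scan import GenomeSequence, random_genome, reverse_complement


def perfect_target(mirna: str, allow_c_positions: bool = True) -> str:
    """The purine-strand DNA target maximizing reverse-Hoogsteen units.

    Under the antiparallel registration the maximizing target is simply the
    reverse of the miRNA with U -> T: every purine position of the miRNA
    then faces its own identity and forms a favorable unit, while pyrimidine
    positions (C/U) cannot be favorable under the purine third-strand motif
    whatever the target base.  With ``allow_c_positions`` (default) those
    positions keep the mirrored pyrimidine, like the validated 21-unit
    target that spans a C; with ``allow_c_positions=False`` they are
    replaced by G so the planted tract is pure polypurine.
    """
    seq = mirna.upper().replace("U", "T")
    rev = seq[::-1]
    if allow_c_positions:
        return rev
    return "".join(b if b in "AG" else "G" for b in rev)


@dataclass
class PlantingPlan:
    """Targets to substitute into a uniform random background."""

    background_length: int
    planted: List[Tuple[str, str, int, str]] = field(default_factory=list)
    #: each entry: (mirna_id, target_sequence, position, strand)
    seed: int = 0

    def __post_init__(self):
        intervals = []
        for mid, target, pos, strand in self.planted:
            if strand not in "+-":
                raise ValueError(f"bad strand {strand!r} for {mid}")
            if pos < 0 or pos + len(target) > self.background_length:
                raise ValueError(f"plant for {mid} exceeds the background")
            intervals.append((pos, pos + len(target), mid))
        intervals.sort()
        for (s1, e1, m1), (s2, e2, m2) in zip(intervals, intervals[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping plants: {m1} and {m2}")


def plant_genome(
    plan: PlantingPlan,
    mirnas: Optional[Dict[str, str]] = None,
    name: str = "planted",
) -> Tuple[GenomeSequence, pd.DataFrame]:
    """Substitute targets into random background; return genome + truth.

    The truth table records each planted interval and, when the miRNA
    catalogue is supplied, the unit count expected at the planted
    registration (reverse-Hoogsteen, antiparallel, full overlap).
    """
    genome = random_genome(plan.background_length, plan.seed, name=name)
    seq = list(genome.sequence)
    rows = []
    for mid, target, pos, strand in plan.planted:
        target = target.upper().replace("U", "T")
        insert = target if strand == "+" else reverse_complement(target)
        seq[pos : pos + len(target)] = insert
        expected = None
        if mirnas is not None and mid in mirnas:
            expected = count_favorable(
                mirnas[mid], target, BindingMode.REVERSE_HOOGSTEEN,
                Orientation.ANTIPARALLEL, 0,
            ).n_units
        rows.append(
            {
                "chrom": name,
                "start": pos,
                "end": pos + len(target),
                "strand": strand,
                "mirna_id": mid,
                "expected_n_units": expected,
            }
        )
    truth = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "mirna_id", "expected_n_units"]
    )
    return GenomeSequence(name, "".join(seq)), truth


def random_mirnas(
    n: int,
    seed: int,
    length: int = 22,
    purine_fraction: float = 0.5,
    prefix: str = "mir-sim",
) -> Dict[str, str]:
    """Random miRNA catalogue with controlled purine content.

    Bases are drawn with P(A) = P(G) = purine_fraction/2 and
    P(C) = P(U) = (1-purine_fraction)/2.
    """
    rng = np.random.default_rng(seed)
    pr = purine_fraction / 2
    py = (1 - purine_fraction) / 2
    bases = np.array(list("AGCU"))
    out = {}
    for i in range(n):
        seq = "".join(rng.choice(bases, size=length, p=[pr, pr, py, py]))
        out[f"{prefix}-{i + 1:03d}"] = seq
    return out


@dataclass
class ExpressionSimSpec:
    """Design of a two-cohort expression simulation.

    ``planted_pairs`` entries are (mirna_id, gene_id, rho_target): the
    Spearman correlation aimed for in every cohort.  Each gene may carry at
    most one planted miRNA; non-planted pairs are independent.
    """

    n_samples: Tuple[int, int] = (100, 100)
    n_genes: int = 50
    n_mirnas: int = 20
    planted_pairs: List[Tuple[str, str, float]] = field(default_factory=list)
    gene_prefix: str = "GENE"
    mirna_prefix: str = "mir-sim"

    def gene_ids(self) -> List[str]:
        return [f"{self.gene_prefix}{i + 1:04d}" for i in range(self.n_genes)]

    def mirna_ids(self) -> List[str]:
        return [f"{self.mirna_prefix}-{i + 1:03d}" for i in range(self.n_mirnas)]

    def __post_init__(self):
        genes = set(self.gene_ids())
        mirnas = set(self.mirna_ids())
        seen_genes = set()
        for mid, gid, rho in self.planted_pairs:
            if mid not in mirnas or gid not in genes:
                raise ValueError(f"planted pair ({mid}, {gid}) references unknown ids")
            if abs(rho) >= 1:
                raise ValueError("|rho_target| must be < 1")
            if gid in seen_genes:
                raise ValueError(f"gene {gid} planted more than once")
            seen_genes.add(gid)


def _latent_pearson(rho_s: float, n: int) -> float:
    """Latent bivariate-normal correlation whose *sample* Spearman at size n
    has expectation rho_s.

    The population relation is rho_s = (6/pi) asin(r/2); at finite n the
    sample coefficient is attenuated, with expectation
    (6 / (pi (n+1))) [ (n-2) asin(r/2) + asin(r) ]  (Moran's formula),
    so the latent r is found by inverting that expectation.
    """
    if rho_s == 0:
        return 0.0

    def expected(r: float) -> float:
        return (6.0 / (np.pi * (n + 1))) * ((n - 2) * np.arcsin(r / 2) + np.arcsin(r))

    from scipy.optimize import brentq

    sign = 1.0 if rho_s > 0 else -1.0
    return sign * brentq(lambda r: expected(r) - abs(rho_s), 0.0, 1.0 - 1e-12)


def simulate_cohorts(
    spec: ExpressionSimSpec, seed: int
) -> Tuple[ExpressionCohort, ExpressionCohort, pd.DataFrame]:
    """Two independent cohorts with the same planted correlation structure.

    Latent standard normals are generated per miRNA; a planted gene is a
    correlated mixture of its miRNA's latent vector and fresh noise, with
    the Pearson latent correlation chosen so the population Spearman equals
    ``rho_target``.  Values are mapped affinely onto a log-intensity-like
    scale (location 8, scale 2), which preserves all ranks.
    """
    rng = np.random.default_rng(seed)
    gene_ids = spec.gene_ids()
    mirna_ids = spec.mirna_ids()
    planted = {gid: (mid, rho) for mid, gid, rho in spec.planted_pairs}
    cohorts = []
    for c, n in enumerate(spec.n_samples):
        samples = [f"C{c + 1}_S{i + 1:03d}" for i in range(n)]
        M = rng.standard_normal((n, spec.n_mirnas))
        G = np.empty((n, spec.n_genes))
        midx = {m: i for i, m in enumerate(mirna_ids)}
        for j, gid in enumerate(gene_ids):
            noise = rng.standard_normal(n)
            if gid in planted:
                mid, rho_s = planted[gid]
                r = _latent_pearson(rho_s, n)
                G[:, j] = r * M[:, midx[mid]] + np.sqrt(1 - r**2) * noise
            else:
                G[:, j] = noise
        cohorts.append(
            ExpressionCohort(
                cohort_id=f"cohort{c + 1}",
                genes=pd.DataFrame(8.0 + 2.0 * G, index=samples, columns=gene_ids),
                mirnas=pd.DataFrame(8.0 + 2.0 * M, index=samples, columns=mirna_ids),
            )
        )
    truth = pd.DataFrame(
        [
            {"mirna_id": mid, "gene_id": gid, "rho_target": rho}
            for mid, gid, rho in spec.planted_pairs
        ],
        columns=["mirna_id", "gene_id", "rho_target"],
    )
    return cohorts[0], cohorts[1], truth


def default_planting_plan(
    mirnas: Dict[str, str],
    background_length: int,
    seed: int,
    spacing: Optional[int] = None,
) -> PlantingPlan:
    """Evenly spaced perfect targets, one per miRNA, alternating strands."""
    ids = sorted(mirnas)
    if spacing is None:
        spacing = background_length // (len(ids) + 1)
    planted = []
    for i, mid in enumerate(ids):
        target = perfect_target(mirnas[mid])
        pos = (i + 1) * spacing
        planted.append((mid, target, pos, "+" if i % 2 == 0 else "-"))
    return PlantingPlan(background_length=background_length, planted=planted, seed=seed)
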