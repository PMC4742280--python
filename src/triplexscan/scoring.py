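"""Heuristic score and additive pair-wise binding energy for alignments.

The heuristic score is purely a count statistic: ``points_per_unit`` times
the number of favorable triplex-forming units, with no positional or seed
weighting (the duplex-DNA/microRNA interaction is symmetric, so there is no
seed region to privilege).  The default calibration pins 7 units to a score
of 140, the reporting threshold.

The binding energy is the sum of a per-unit energy over the favorable
positions of the alignment; unfavorable positions are not base pairs of the
triplex and contribute nothing.  Energies come from a tab-delimited table of
(mode, purine base, third base) -> kcal/mol.  The packaged default table
carries synthetic stand-in values (see the data file header); all absolute-
energy results are configuration-sensitive by design.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

from .pairing import FAVORABLE_UNITS, BindingMode, TriplexAlignment

EnergyKey = Tuple[BindingMode, str, str]

_DEFAULT_TABLE_RESOURCE = "energy_defaults_synthetic.tsv"


@dataclass
class ScoreParameters:
    """Scoring calibration and reporting thresholds.

    ``min_score = points_per_unit * min_units`` under the defaults
    (140 = 20 x 7).  ``min_energy`` is an optional additional reporting
    cut-off (site kept when energy <= min_energy); disabled by default.
    """

    points_per_unit: float = 20.0
    min_score: float = 140.0
    min_units: int = 7
    min_energy: Optional[float] = None

    def __post_init__(self):
        if self.points_per_unit <= 0:
            raise ValueError("points_per_unit must be positive")


@dataclass
class EnergyTable:
    """Per-unit triplex energies in kcal/mol, keyed (mode, purine, third)."""

    entries: Dict[EnergyKey, float] = field(default_factory=dict)
    source_label: str = ""

    def __post_init__(self):
        missing = [k for k in FAVORABLE_UNITS if tuple(k) not in self.entries]
        if missing:
            raise ValueError(
                "energy table is missing favorable units: "
                + ", ".join(f"{m.value} {p}:{z}" for m, p, z in sorted(missing))
            )

    def get(self, mode: BindingMode, purine_base: str, third_base: str) -> float:
        key = (BindingMode(mode), purine_base.upper(), third_base.upper())
        try:
            return self.entries[key]
        except KeyError:
            raise KeyError(
                f"no energy entry for {key[0].value} {key[1]}:{key[2]}"
            ) from None

    @classmethod
    def from_file(cls, path) -> "EnergyTable":
        entries: Dict[EnergyKey, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if cols[0] == "mode":  # header row
                    continue
                if len(cols) != 4:
                    raise ValueError(f"malformed energy table row: {line!r}")
                mode, pb, zb, e = cols
                entries[(BindingMode(mode), pb.upper(), zb.upper())] = float(e)
        return cls(entries=entries, source_label=str(path))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("mode\tpurine_base\tthird_base\tenergy_kcal_mol\n")
            for (mode, pb, zb), e in sorted(
                self.entries.items(), key=lambda kv: (kv[0][0].value, kv[0][1], kv[0][2])
            ):
                fh.write(f"{mode.value}\t{pb}\t{zb}\t{e!r}\n")

    @classmethod
    def default(cls) -> "EnergyTable":
        ref = importlib.resources.files("triplexscan.data") / _DEFAULT_TABLE_RESOURCE
        with importlib.resources.as_file(ref) as path:
            table = cls.from_file(path)
        table.source_label = "packaged synthetic defaults"
        return table


def heuristic_score(
    alignment: TriplexAlignment, params: Optional[ScoreParameters] = None
) -> float:
    """Score = points_per_unit x favorable-unit count.  No weighting."""
    if params is None:
        params = ScoreParameters()
    if alignment.n_units != sum(alignment.match_vector):
        raise ValueError("alignment n_units inconsistent with its match_vector")
    return params.points_per_unit * alignment.n_units


def binding_energy(alignment: TriplexAlignment, table: Optional[EnergyTable] = None) -> float:
    """Sum the per-unit table energies over the favorable positions only."""
    if table is None:
        table = EnergyTable.default()
    total = 0.0
    for mode, tb, zb in alignment.units():
        total += table.get(mode, tb, zb)
    return total


def passes_threshold(
    alignment: TriplexAlignment, params: Optional[ScoreParameters] = None
) -> bool:
    """True iff the alignment's score (and optional energy) pass reporting cuts."""
    if params is None:
        params = ScoreParameters()
    score = alignment.score if alignment.score is not None else heuristic_score(alignment, params)
    if score < params.min_score:
        return False
    if params.min_energy is not None:
        energy = alignment.energy
        if energy is None:
            energy = binding_energy(alignment)
        if energy > params.min_energy:
            return False
    return True
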