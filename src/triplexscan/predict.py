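"""Single-pair prediction: one miRNA against one duplex strand.

The user supplies a microRNA sequence and one strand of a duplex DNA
region.  Both the given strand and its reverse complement are evaluated as
the potential purine strand, under every requested mode and orientation and
every registration, and the passing (or all) alignments are reported sorted
by unit count (descending) then energy (ascending).  When a fitted grade
model is supplied, each alignment also receives an interpolated grade.
"""

from __future__ import annotations

import re
from typing import List, Optional, Sequence

import pandas as pd

from .grading import GradeModel, interpolate_grade
from .pairing import BindingMode, Orientation, count_favorable
from .scan import reverse_complement
from .scoring import EnergyTable, ScoreParameters, binding_energy, heuristic_score


def _validate(seq: str, what: str, alphabet: str) -> str:
    s = seq.upper()
    m = re.search(f"[^{alphabet}]", s)
    if not s:
        raise ValueError(f"empty {what} sequence")
    if m:
        raise ValueError(
            f"invalid {what} symbol {s[m.start()]!r} at position {m.start()}"
        )
    return s


def predict_pair(
    mirna_sequence: str,
    duplex_strand_sequence: str,
    params: Optional[ScoreParameters] = None,
    table: Optional[EnergyTable] = None,
    modes: Optional[Sequence[BindingMode]] = None,
    orientations: Optional[Sequence[Orientation]] = None,
    model: Optional[GradeModel] = None,
    min_units: int = 1,
    mirna_id: str = "query",
) -> pd.DataFrame:
    """All alignments of one miRNA against one duplex region.

    Coordinates in the report refer to the strand as given; alignments
    against the reverse complement are marked strand '-' with coordinates
    mapped back onto the given strand.  Deterministic: sorted by
    (n_units desc, energy asc, strand, start).
    """
    mirna = _validate(mirna_sequence, "miRNA", "ACGTU")
    duplex = _validate(duplex_strand_sequence, "duplex", "ACGTN")
    if params is None:
        params = ScoreParameters()
    if table is None:
        table = EnergyTable.default()
    if modes is None:
        modes = list(BindingMode)
    if orientations is None:
        orientations = list(Orientation)
    L = len(duplex)
    rows = []
    for strand, target in (("+", duplex), ("-", reverse_complement(duplex))):
        for mode in modes:
            for orient in orientations:
                for off in range(-(len(mirna) - 1), L):
                    try:
                        aln = count_favorable(mirna, target, mode, orient, off, mirna_id)
                    except ValueError:
                        continue
                    if aln.n_units < min_units:
                        continue
                    aln.score = heuristic_score(aln, params)
                    aln.energy = binding_energy(aln, table)
                    if strand == "+":
                        s, e = aln.target_start, aln.target_end
                    else:
                        s, e = L - aln.target_end, L - aln.target_start
                    row = {
                        "mirna_id": mirna_id,
                        "start": s,
                        "end": e,
                        "strand": strand,
                        "mode": mode.value,
                        "orientation": orient.value,
                        "n_units": aln.n_units,
                        "score": aln.score,
                        "energy_kcal_mol": aln.energy,
                        "passes": aln.score >= params.min_score,
                    }
                    if model is not None:
                        row["grade"] = interpolate_grade(aln.score, aln.energy, model)
                    rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df.sort_values(
        ["n_units", "energy_kcal_mol", "strand", "start", "mode", "orientation"],
        ascending=[False, True, True, True, True, True],
    ).reset_index(drop=True)
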