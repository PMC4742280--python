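"""Base-level Hoogsteen and reverse-Hoogsteen triplex pairing rules.

A triple helix forms when a third nucleic-acid strand (here a microRNA or a
DNA oligo) occupies the major groove of a Watson-Crick duplex.  Pairing is
keyed on the *purine* base of each duplex pair, because only purines present
a second hydrogen-bonding face.  Writing a duplex pair as XY and the third
strand base as Z (XY:Z), the favorable triplex-forming units are:

* Hoogsteen (pyrimidine third-strand motif):      TA:U and CG:C
* Reverse Hoogsteen (purine third-strand motif):  TA:A and CG:G

A single alignment is counted under one mode only; mixing Hoogsteen and
reverse-Hoogsteen units within one registration is not allowed.  Alignments
are ungapped.  Ambiguity codes (N etc.) are never favorable but do not abort
an alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence


class BindingMode(str, Enum):
    """The two triplex hydrogen-bonding chemistries."""

    HOOGSTEEN = "hoogsteen"
    REVERSE_HOOGSTEEN = "reverse_hoogsteen"


class Orientation(str, Enum):
    """Direction of the third strand relative to the purine strand.

    ``ANTIPARALLEL``: third strand 5'->3' runs against the purine strand
    3'->5' (the geometry supported by the molecular model).  ``PARALLEL`` is
    the co-directional registration.
    """

    ANTIPARALLEL = "antiparallel"
    PARALLEL = "parallel"


#: Favorable (mode, duplex purine base, third-strand base) triplets.  Third
#: strand bases are canonicalized to the RNA alphabet (T -> U) before lookup.
FAVORABLE_UNITS = frozenset(
    {
        (BindingMode.HOOGSTEEN, "A", "U"),
        (BindingMode.HOOGSTEEN, "G", "C"),
        (BindingMode.REVERSE_HOOGSTEEN, "A", "A"),
        (BindingMode.REVERSE_HOOGSTEEN, "G", "G"),
    }
)

_PURINES = ("A", "G")


def canonicalize_third(base: str) -> str:
    """Upper-case a third-strand base and map T to U."""
    b = base.upper()
    return "U" if b == "T" else b


def is_favorable(mode: BindingMode, purine_base: str, third_base: str) -> bool:
    """Look up the pairing-rule table for one duplex pair / third base.

    ``purine_base`` must be the purine of the Watson-Crick pair (A of T.A,
    G of C.G); any other symbol raises, since a duplex pair is keyed by its
    purine.  Unknown or ambiguous third-strand symbols are never favorable.
    """
    mode = BindingMode(mode)
    pb = purine_base.upper()
    if pb not in _PURINES:
        raise ValueError(
            f"duplex pair must be keyed by its purine (A or G), got {purine_base!r}"
        )
    zb = canonicalize_third(third_base)
    if zb not in ("A", "C", "G", "U"):
        return False
    return (mode, pb, zb) in FAVORABLE_UNITS


def _favorable_relaxed(mode: BindingMode, target_base: str, third_base: str) -> bool:
    # Scanning helper: a non-purine base on the (majority-purine) target
    # strand simply yields an unfavorable unit instead of an error.  This is
    # what lets a site span an interrupting C, as the validated 21-unit
    # target does.
    if target_base not in _PURINES:
        return False
    zb = canonicalize_third(third_base)
    if zb not in ("A", "C", "G", "U"):
        return False
    return (mode, target_base, zb) in FAVORABLE_UNITS


@dataclass
class TriplexAlignment:
    """One ungapped registration of a third strand against a purine strand.

    ``offset`` is the 0-based position on the purine target where the
    (orientation-adjusted) third strand starts; it may be negative for
    alignments overhanging the left edge.  ``match_vector`` holds one boolean
    per overlapping position, in target order; ``target_bases`` and
    ``third_bases`` are the paired bases over the overlap, also in target
    order.  ``score`` and ``energy`` are filled in by the scoring module.
    """

    mirna_id: str
    mode: BindingMode
    orientation: Orientation
    offset: int
    match_vector: list = field(default_factory=list)
    target_bases: str = ""
    third_bases: str = ""
    n_units: int = 0
    score: Optional[float] = None
    energy: Optional[float] = None

    @property
    def target_start(self) -> int:
        return max(0, self.offset)

    @property
    def target_end(self) -> int:
        return self.target_start + len(self.match_vector)

    def units(self) -> Iterable[tuple]:
        """Yield (mode, target_base, third_base) for each favorable position."""
        for ok, tb, zb in zip(self.match_vector, self.target_bases, self.third_bases):
            if ok:
                yield (self.mode, tb, zb)


def _clean_target(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _clean_third(seq: str) -> str:
    return seq.upper().replace("T", "U")


def count_favorable(
    third: str,
    purine_target: str,
    mode: BindingMode,
    orientation: Orientation = Orientation.ANTIPARALLEL,
    offset: int = 0,
    mirna_id: str = "",
) -> TriplexAlignment:
    """Count favorable triplex-forming units at one fixed registration.

    For the antiparallel orientation, overlap position ``i`` (counted from
    ``offset`` on the target) pairs ``purine_target[offset+i]`` with
    ``third[len(third)-1-i]``; the parallel orientation pairs it with
    ``third[i]``.  Unfavorable interior positions contribute zero units but
    do not terminate the alignment.
    """
    mode = BindingMode(mode)
    orientation = Orientation(orientation)
    third_c = _clean_third(third)
    target_c = _clean_target(purine_target)
    if not third_c or not target_c:
        raise ValueError("empty sequence")
    lo = max(0, offset)
    hi = min(len(target_c), offset + len(third_c))
    if lo >= hi:
        raise ValueError(
            f"offset {offset} places no overlap between a {len(third_c)} nt third "
            f"strand and a {len(target_c)} nt target"
        )
    match = []
    tbs = []
    zbs = []
    n3 = len(third_c)
    for p in range(lo, hi):
        k = p - offset
        j = n3 - 1 - k if orientation is Orientation.ANTIPARALLEL else k
        tb = target_c[p]
        zb = third_c[j]
        match.append(_favorable_relaxed(mode, tb, zb))
        tbs.append(tb)
        zbs.append(zb)
    return TriplexAlignment(
        mirna_id=mirna_id,
        mode=mode,
        orientation=orientation,
        offset=offset,
        match_vector=match,
        target_bases="".join(tbs),
        third_bases="".join(zbs),
        n_units=int(sum(match)),
    )


_MODE_ORDER = {BindingMode.HOOGSTEEN: 0, BindingMode.REVERSE_HOOGSTEEN: 1}
_ORIENT_ORDER = {Orientation.ANTIPARALLEL: 0, Orientation.PARALLEL: 1}


def best_alignment(
    third: str,
    purine_target: str,
    modes: Optional[Sequence[BindingMode]] = None,
    orientations: Optional[Sequence[Orientation]] = None,
    table=None,
    mirna_id: str = "",
) -> TriplexAlignment:
    """Exhaustively maximize the unit count over offsets, modes, orientations.

    Every offset with at least one overlapping position is evaluated
    (including overhanging registrations at both edges).  Ties are broken by
    lower energy, then smaller offset, then mode order (Hoogsteen before
    reverse Hoogsteen), then orientation order (antiparallel first).  Energy
    for tie-breaking uses ``table`` or the packaged default.
    """
    from .scoring import EnergyTable, binding_energy

    if table is None:
        table = EnergyTable.default()
    if modes is None:
        modes = list(BindingMode)
    if orientations is None:
        orientations = list(Orientation)
    modes = [BindingMode(m) for m in modes]
    orientations = [Orientation(o) for o in orientations]
    third_c = _clean_third(third)
    target_c = _clean_target(purine_target)
    if not third_c or not target_c:
        raise ValueError("empty sequence")

    best = None
    best_key = None
    for mode in modes:
        for orient in orientations:
            for off in range(-(len(third_c) - 1), len(target_c)):
                aln = count_favorable(third_c, target_c, mode, orient, off, mirna_id)
                aln.energy = binding_energy(aln, table)
                key = (
                    -aln.n_units,
                    aln.energy,
                    aln.offset,
                    _MODE_ORDER[mode],
                    _ORIENT_ORDER[orient],
                )
                if best_key is None or key < best_key:
                    best, best_key = aln, key
    return best
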