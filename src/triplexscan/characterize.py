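"""Sequence-composition characterization of triplex-forming microRNAs.

The miRNAs behind the top-graded sites of a scan are profiled (purine,
GC and GU content, length, per-base fractions) and compared against the
full miRNA catalogue with two-sample proportion tests.  The headline
classes are purine:pyrimidine imbalance (>75% of either), extreme GC
(<25% or >75%) and extreme GU content.  Each reported site counts once,
so a miRNA with many sites contributes per site.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Set, Tuple

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_PURINES = {"A", "G"}


@dataclass
class CompositionProfile:
    """Base-composition summary of one miRNA (T canonicalized to U)."""

    mirna_id: str
    length: int
    purine_fraction: float
    pyrimidine_fraction: float
    gc_fraction: float
    gu_fraction: float
    fraction_a: float
    fraction_c: float
    fraction_g: float
    fraction_u: float


def composition(mirna: str, mirna_id: str = "") -> CompositionProfile:
    """Exact base counts divided by length."""
    seq = mirna.upper().replace("T", "U")
    if not seq:
        raise ValueError("empty miRNA sequence")
    bad = set(seq) - {"A", "C", "G", "U"}
    if bad:
        raise ValueError(f"non-nucleotide symbol(s) {sorted(bad)} in {mirna_id or mirna!r}")
    n = len(seq)
    counts = {b: seq.count(b) for b in "ACGU"}
    return CompositionProfile(
        mirna_id=mirna_id,
        length=n,
        purine_fraction=(counts["A"] + counts["G"]) / n,
        pyrimidine_fraction=(counts["C"] + counts["U"]) / n,
        gc_fraction=(counts["G"] + counts["C"]) / n,
        gu_fraction=(counts["G"] + counts["U"]) / n,
        fraction_a=counts["A"] / n,
        fraction_c=counts["C"] / n,
        fraction_g=counts["G"] / n,
        fraction_u=counts["U"] / n,
    )


def imbalance_class(profile: CompositionProfile, threshold: float = 0.75) -> bool:
    """True when purine or pyrimidine content exceeds the threshold."""
    return profile.purine_fraction > threshold or profile.pyrimidine_fraction > threshold


def extreme_class(fraction: float, low: float = 0.25, high: float = 0.75) -> bool:
    """True when a content fraction is below ``low`` or above ``high``."""
    return fraction < low or fraction > high


def proportion_test(x1: int, n1: int, x2: int, n2: int) -> Tuple[float, float]:
    """Two-sample test for equality of proportions with continuity correction.

    Yates-corrected chi-squared on the 2x2 table, 1 df, two-sided; matches
    R's ``prop.test``.  Degenerate margins (all successes or all failures
    pooled) carry no evidence and return (0, 1) with a warning.
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2) or n1 <= 0 or n2 <= 0:
        raise ValueError("require 0 <= x_i <= n_i and n_i > 0")
    table = [[x1, n1 - x1], [x2, n2 - x2]]
    if x1 + x2 == 0 or (n1 - x1) + (n2 - x2) == 0:
        warnings.warn("degenerate margins in proportion test; p set to 1")
        return 0.0, 1.0
    res = stats.chi2_contingency(table, correction=True)
    return float(res.statistic), float(res.pvalue)


def characterize_hits(
    sites: pd.DataFrame,
    all_mirnas: Dict[str, str],
    grades: Optional[Iterable[int]] = None,
    imbalance_threshold: float = 0.75,
    extreme_low: float = 0.25,
    extreme_high: float = 0.75,
) -> pd.DataFrame:
    """Compare composition of hit miRNAs (per-site weighted) to the catalogue.

    ``sites`` is a graded site table (needs ``mirna_id`` and ``grade``
    columns); ``grades`` selects which grades count as hits (default 1-4,
    the top percent).  Returns one row per metric with the hit value, the
    catalogue value, and (for the class metrics) the proportion-test
    statistic and p-value.
    """
    if grades is None:
        grades = {1, 2, 3, 4}
    grades = set(int(g) for g in grades)
    profiles = {mid: composition(seq, mid) for mid, seq in all_mirnas.items()}
    hit_ids: List[str] = [
        str(m)
        for m, g in zip(sites["mirna_id"], sites["grade"])
        if int(g) in grades
    ]
    rows = []
    if not hit_ids:
        logger.warning("no sites at the requested grades; empty summary")
        return pd.DataFrame(
            columns=["metric", "hits_value", "catalog_value", "statistic", "p_value"]
        )
    missing = set(hit_ids) - set(profiles)
    if missing:
        raise KeyError(f"site miRNAs absent from catalogue: {sorted(missing)[:5]}")
    hits = [profiles[m] for m in hit_ids]
    cat = list(profiles.values())
    n1, n2 = len(hits), len(cat)

    class_defs = [
        ("purine_pyrimidine_imbalance_gt75",
         lambda p: imbalance_class(p, imbalance_threshold)),
        ("gc_extreme_lt25_gt75",
         lambda p: extreme_class(p.gc_fraction, extreme_low, extreme_high)),
        ("gu_extreme_lt25_gt75",
         lambda p: extreme_class(p.gu_fraction, extreme_low, extreme_high)),
    ]
    for name, fn in class_defs:
        x1 = sum(fn(p) for p in hits)
        x2 = sum(fn(p) for p in cat)
        stat, p = proportion_test(x1, n1, x2, n2)
        rows.append(
            {
                "metric": name,
                "hits_value": x1 / n1,
                "catalog_value": x2 / n2,
                "statistic": stat,
                "p_value": p,
            }
        )
    mean_fields = [
        "length",
        "purine_fraction",
        "gc_fraction",
        "gu_fraction",
        "fraction_a",
        "fraction_c",
        "fraction_g",
        "fraction_u",
    ]
    for fld in mean_fields:
        rows.append(
            {
                "metric": f"mean_{fld}",
                "hits_value": sum(getattr(p, fld) for p in hits) / n1,
                "catalog_value": sum(getattr(p, fld) for p in cat) / n2,
                "statistic": float("nan"),
                "p_value": float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["metric", "hits_value", "catalog_value", "statistic", "p_value"])
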