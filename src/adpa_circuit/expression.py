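"""Relative-expression arithmetic: 2^dCT qPCR quantification against the
hrdB reference, fold changes, EGFP/OD normalization, replicate summaries
and prevalence percentages.

Convention: relative expression is 2**(-(CT_target - CT_ref)), so a target
amplifying 5 cycles earlier than the reference is 32-fold more abundant.
Amplification efficiency is fixed at 2 (perfect doubling per cycle).
Replicates are quantified individually and then averaged, matching the
"three independent repeats, average +/- SD" reporting style.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QpcrSample",
    "ReporterReading",
    "relative_expression",
    "fold_change",
    "egfp_normalized",
    "summarize_replicates",
    "prevalence",
    "qpcr_table",
]

_CT_RANGE = (0.0, 45.0)


@dataclass(frozen=True)
class QpcrSample:
    """One replicate's cycle thresholds for a target gene and the reference."""

    ct_target: float
    ct_ref: float
    condition: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        for name in ("ct_target", "ct_ref"):
            v = getattr(self, name)
            if not math.isfinite(v) or not _CT_RANGE[0] < v < _CT_RANGE[1]:
                raise ValueError(f"{name}={v} outside plausible CT range (0, 45)")


@dataclass(frozen=True)
class ReporterReading:
    """EGFP fluorescence reading with the culture density it came from."""

    fluorescence: float
    od450: float
    condition: str = ""

    def __post_init__(self) -> None:
        if not self.od450 > 0:
            raise ValueError("od450 must be > 0")
        if not math.isfinite(self.fluorescence) or self.fluorescence < 0:
            raise ValueError("fluorescence must be finite and >= 0")


def relative_expression(s: QpcrSample) -> float:
    """Expression of the target relative to the reference: 2**(ct_ref - ct_target)."""
    return 2.0 ** (-(s.ct_target - s.ct_ref))


def fold_change(rel_test: float, rel_control: float) -> float:
    """Ratio of relative expressions (test over control)."""
    if rel_control <= 0:
        raise ValueError("rel_control must be > 0")
    return rel_test / rel_control


def egfp_normalized(r: ReporterReading) -> float:
    """Fluorescence per unit cell density (fluorescence / OD450)."""
    return r.fluorescence / r.od450


def summarize_replicates(values) -> tuple[float, float, int]:
    """Mean, sample SD (ddof=1) and n.  SD is NaN for a single replicate."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("no replicate values")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size >= 2 else math.nan
    return mean, sd, int(vals.size)


def prevalence(n_with: int, n_total: int) -> float:
    """Percentage of strains carrying the gene, truncated at 2 decimals.

    Truncation (not rounding) reproduces the convention of the source
    survey (2,752 of 3,033 strains = 90.73%); computed in exact integer
    arithmetic so 2752/3033 -> 90.73 and 3033/3033 -> 100.00.
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_with <= n_total:
        raise ValueError("need 0 <= n_with <= n_total")
    return (10000 * n_with // n_total) / 100.0


def qpcr_table(ct: pd.DataFrame, target: str, ref: str = "hrdB",
               control: str | None = None) -> pd.DataFrame:
    """Per-condition relative expression (and fold vs control) from a CT table.

    ``ct`` has columns condition, replicate, gene, ct.  Each replicate is
    quantified as 2^-(dCT) against its own reference reading, then
    replicates are summarized.  When ``control`` is given, a ``fold``
    column relative to the control condition's mean is added.
    """
    required = {"condition", "replicate", "gene", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"CT table needs columns {sorted(required)}")
    rows = []
    for cond, grp in ct.groupby("condition", sort=False):
        rels = []
        for rep, rep_grp in grp.groupby("replicate"):
            by_gene = rep_grp.set_index("gene")["ct"]
            if target not in by_gene.index or ref not in by_gene.index:
                raise ValueError(
                    f"condition {cond!r} replicate {rep} lacks {target!r} or {ref!r}")
            s = QpcrSample(ct_target=float(by_gene[target]),
                           ct_ref=float(by_gene[ref]),
                           condition=str(cond), replicate=int(rep))
            rels.append(relative_expression(s))
        mean, sd, n = summarize_replicates(rels)
        rows.append({"condition": cond, "rel_mean": mean, "rel_sd": sd, "n": n})
    out = pd.DataFrame(rows)
    if control is not None:
        if control not in set(out["condition"]):
            raise ValueError(f"control condition {control!r} not in table")
        base = float(out.loc[out["condition"] == control, "rel_mean"].iloc[0])
        out["fold"] = [fold_change(v, base) for v in out["rel_mean"]]
    return out
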