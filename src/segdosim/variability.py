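"""Inter- vs intra-observer contour agreement and per-lesion uncertainty.

Pairs of reads of the same lesion are compared with the Dice coefficient:

* *inter-observer* pairs are reads by **different readers** of the same
  lesion **within the same round** (only readers who contoured in that
  round contribute);
* *intra-observer* pairs are reads by the **same reader** of the same lesion
  **across rounds**.

Under the default 7-read design (A:3, B:3, C:1) each lesion yields 5 inter
pairs (AB, AC, BC in round 1; AB in rounds 2 and 3) and 6 intra pairs
(C(3,2) for each of A and B).

Per-lesion measurement uncertainty is the coefficient of variation across a
lesion's reads, CV% = 100 * SD / mean (sample SD, n-1 denominator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .masks import ReadRecord, dice_coefficient


@dataclass(frozen=True)
class DicePair:
    """One Dice comparison between two reads of the same lesion."""

    lesion_id: str
    kind: str  # "inter" | "intra"
    reader_a: str
    reader_b: str
    round_a: int
    round_b: int
    dice: Optional[float] = None

    def __post_init__(self):
        if self.kind == "inter":
            if self.reader_a == self.reader_b or self.round_a != self.round_b:
                raise ValueError("inter pairs need different readers, same round")
        elif self.kind == "intra":
            if self.reader_a != self.reader_b or self.round_a == self.round_b:
                raise ValueError("intra pairs need the same reader, different rounds")
        else:
            raise ValueError("kind must be 'inter' or 'intra'")


def _usable(reads: Sequence[ReadRecord]) -> list[ReadRecord]:
    kept = []
    for r in reads:
        if r.volume_ml <= 0:
            warnings.warn(
                f"excluding zero-volume read ({r.lesion_id}, {r.reader_id}, round {r.round})",
                stacklevel=3,
            )
            continue
        kept.append(r)
    return kept


def enumerate_pairs(reads: Sequence[ReadRecord], kind: str) -> list[tuple[ReadRecord, ReadRecord]]:
    """All inter- or intra-observer read pairs under the pairing rules above.

    Zero-volume reads are excluded with a warning. The list may be empty
    (e.g. no round has two readers).
    """
    if kind not in ("inter", "intra"):
        raise ValueError("kind must be 'inter' or 'intra'")
    pairs: list[tuple[ReadRecord, ReadRecord]] = []
    reads = _usable(reads)
    lesion_ids = sorted({r.lesion_id for r in reads})
    for lid in lesion_ids:
        lesion_reads = [r for r in reads if r.lesion_id == lid]
        if kind == "inter":
            rounds = sorted({r.round for r in lesion_reads})
            for rnd in rounds:
                in_round = sorted(
                    (r for r in lesion_reads if r.round == rnd), key=lambda r: r.reader_id
                )
                pairs.extend(combinations(in_round, 2))
        else:
            readers = sorted({r.reader_id for r in lesion_reads})
            for reader in readers:
                by_reader = sorted(
                    (r for r in lesion_reads if r.reader_id == reader), key=lambda r: r.round
                )
                pairs.extend(combinations(by_reader, 2))
    return pairs


def dice_pairs(reads: Sequence[ReadRecord], kind: str) -> list[DicePair]:
    """Enumerate pairs and evaluate the Dice coefficient of each."""
    out = []
    for a, b in enumerate_pairs(reads, kind):
        if a.mask is None or b.mask is None:
            raise ValueError(f"read ({a.lesion_id}, {a.reader_id}) carries no mask")
        out.append(
            DicePair(
                lesion_id=a.lesion_id,
                kind=kind,
                reader_a=a.reader_id,
                reader_b=b.reader_id,
                round_a=a.round,
                round_b=b.round,
                dice=dice_coefficient(a.mask, b.mask),
            )
        )
    return out


def pairs_table(pairs: Sequence[DicePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lesion_id": p.lesion_id,
                "kind": p.kind,
                "reader_a": p.reader_a,
                "reader_b": p.reader_b,
                "round_a": p.round_a,
                "round_b": p.round_b,
                "dice": p.dice,
            }
            for p in pairs
        ]
    )


def compare_dice(inter_values: Sequence[float], intra_values: Sequence[float]):
    """Welch two-sample t-test of mean inter- vs intra-observer Dice.

    Returns ``(t, p)`` with the statistic oriented as inter minus intra, so
    t < 0 when readers agree with themselves more than with each other.
    """
    inter = np.asarray(inter_values, dtype=float)
    intra = np.asarray(intra_values, dtype=float)
    if inter.size < 2 or intra.size < 2:
        raise ValueError("each group needs at least 2 values")
    if inter.std(ddof=1) == 0 and intra.std(ddof=1) == 0:
        if np.allclose(inter.mean(), intra.mean()):
            return 0.0, 1.0
        raise ValueError("degenerate zero-variance groups")
    res = stats.ttest_ind(inter, intra, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def lesion_cv(values: Sequence[float]) -> float:
    """Coefficient of variation in %: 100 * sample SD / mean.

    Requires at least two values and a positive mean; unit-invariant.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 values")
    m = v.mean()
    if m <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return 100.0 * v.std(ddof=1) / m


def summarize_lesions(
    reads_table: pd.DataFrame,
    metrics: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-lesion mean, sample SD and CV% of each measurement column.

    ``reads_table`` is long-per-read with one column per metric (e.g.
    volume_ml, diameter_mm, mean_gy, mean_pvc_gy, d10_gy, d90_gy). Every
    lesion must carry at least 2 reads; missing metric values raise with the
    offending read named.
    """
    if metrics is None:
        metrics = [
            c
            for c in reads_table.columns
            if c not in ("lesion_id", "reader_id", "round") and pd.api.types.is_numeric_dtype(reads_table[c])
        ]
    rows = []
    for lid, grp in reads_table.groupby("lesion_id", sort=True):
        if len(grp) < 2:
            raise ValueError(f"lesion {lid} has fewer than 2 reads")
        row: dict = {"lesion_id": lid, "n_reads": len(grp)}
        for m in metrics:
            vals = grp[m]
            if vals.isna().any():
                bad = grp[vals.isna()].iloc[0]
                raise ValueError(
                    f"missing {m} for read ({bad['lesion_id']}, {bad['reader_id']}, round {bad['round']})"
                )
            row[f"{m}_mean"] = float(vals.mean())
            row[f"{m}_sd"] = float(vals.std(ddof=1))
            row[f"{m}_cv_pct"] = lesion_cv(vals.to_numpy())
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_cv_summary(lesion_summary: pd.DataFrame) -> pd.DataFrame:
    """Cohort-level min / mean / max of the per-lesion CVs, per metric."""
    cv_cols = [c for c in lesion_summary.columns if c.endswith("_cv_pct")]
    rows = []
    for c in cv_cols:
        rows.append(
            {
                "metric": c.removesuffix("_cv_pct"),
                "cv_min": float(lesion_summary[c].min()),
                "cv_mean": float(lesion_summary[c].mean()),
                "cv_max": float(lesion_summary[c].max()),
            }
        )
    return pd.DataFrame(rows)
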