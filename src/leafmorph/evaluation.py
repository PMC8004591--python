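"""Accuracy statistics for scanning, segmentation and trait estimation.

Counts: for one plant, ``n1`` typical leaves selected by hand, ``n2`` of
those well scanned, and ``n3`` recovered automatically give the three
accuracy ratios

    R_scan = n2/n1,  R_seg1 = n3/n2,  R_seg2 = n3/n1   (as percentages).

Trait agreement between an automatic estimate ``x`` and a manual
observation ``y`` is summarized by the modeling efficiency
EF = 1 - SSE/SST (1 = perfect, 0 = mean predictor, negative = worse than
the mean), the RMSE in the trait's units, and the MAPE in percent.

:data:`REFERENCE_SURVEY` ships the leaf counts of a twelve-plant pothos
(Epipremnum aureum) survey spanning four canopy-occlusion classes, three
plants per class, as a worked input for the ratio arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import InputError

__all__ = [
    "CountTriple",
    "accuracy_ratios",
    "modeling_efficiency",
    "rmse",
    "mape",
    "round2",
    "REFERENCE_SURVEY",
    "survey_ratio_table",
]


def round2(x: float) -> float:
    """Round half-up to 2 decimals (percentage reporting convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CountTriple:
    """Typical-leaf counts for one plant (or a pooled set of plants).

    ``n1`` manually selected, ``n2`` well scanned, ``n3`` automatically
    selected; ``n0`` optionally records the total leaves on the plant.
    """

    n1: int
    n2: int
    n3: int
    n0: int | None = None

    def __post_init__(self) -> None:
        for name in ("n1", "n2", "n3"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise InputError(f"{name} must be a non-negative integer, got {v}")


def accuracy_ratios(counts: CountTriple) -> tuple[float, float, float]:
    """(R_scan, R_seg1, R_seg2) as percentages rounded half-up to 2 decimals."""
    if counts.n1 == 0 or counts.n2 == 0:
        raise InputError("n1 and n2 must be positive to form the ratios")
    return (
        round2(100.0 * counts.n2 / counts.n1),
        round2(100.0 * counts.n3 / counts.n2),
        round2(100.0 * counts.n3 / counts.n1),
    )


def modeling_efficiency(x, y) -> float:
    """EF = 1 - SSE/SST of estimates ``x`` against observations ``y``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise InputError("modeling efficiency needs at least 2 samples")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise InputError("observations are constant; EF undefined")
    sse = float(((y - x) ** 2).sum())
    return 1.0 - sse / sst


def rmse(x_m, x_a) -> float:
    """Root-mean-square difference, in the trait's units."""
    x_m = np.asarray(x_m, dtype=float)
    x_a = np.asarray(x_a, dtype=float)
    if x_m.shape != x_a.shape:
        raise InputError(f"length mismatch: {x_m.shape} vs {x_a.shape}")
    if x_m.size == 0:
        raise InputError("rmse of empty sequences")
    return float(np.sqrt(np.mean((x_m - x_a) ** 2)))


def mape(x_m, x_a) -> float:
    """Mean absolute percentage error against the manual values, in %."""
    x_m = np.asarray(x_m, dtype=float)
    x_a = np.asarray(x_a, dtype=float)
    if x_m.shape != x_a.shape:
        raise InputError(f"length mismatch: {x_m.shape} vs {x_a.shape}")
    if x_m.size == 0:
        raise InputError("mape of empty sequences")
    if (x_m == 0).any():
        raise InputError("manual value of zero; MAPE undefined")
    return float(np.mean(np.abs((x_m - x_a) / x_m)) * 100.0)


#: Leaf counts of a 12-plant pothos survey: four occlusion groups
#: (none, little, medium, heavy), three plants each.  Each entry is
#: (group, plant_id, CountTriple(n1, n2, n3, n0)).
REFERENCE_SURVEY: list[tuple[str, int, CountTriple]] = [
    ("none", 1, CountTriple(3, 3, 3, n0=3)),
    ("none", 2, CountTriple(6, 6, 6, n0=6)),
    ("none", 3, CountTriple(6, 6, 6, n0=8)),
    ("little", 4, CountTriple(8, 8, 8, n0=10)),
    ("little", 5, CountTriple(10, 10, 10, n0=10)),
    ("little", 6, CountTriple(11, 11, 11, n0=11)),
    ("medium", 7, CountTriple(24, 23, 22, n0=26)),
    ("medium", 8, CountTriple(25, 24, 23, n0=32)),
    ("medium", 9, CountTriple(31, 30, 28, n0=34)),
    ("heavy", 10, CountTriple(37, 35, 32, n0=45)),
    ("heavy", 11, CountTriple(37, 33, 29, n0=50)),
    ("heavy", 12, CountTriple(36, 31, 27, n0=53)),
]


def survey_ratio_table(
    survey: list[tuple[str, int, CountTriple]] | None = None,
) -> dict:
    """Per-plant ratios, per-group means and pooled overall ratios.

    Group means average the unrounded per-plant ratios; the overall row
    pools the raw counts.  All percentages are reported to 2 decimals.
    """
    survey = REFERENCE_SURVEY if survey is None else survey
    per_plant = {}
    groups: dict[str, list[tuple[float, float, float]]] = {}
    tot1 = tot2 = tot3 = 0
    for group, pid, counts in survey:
        raw = (
            100.0 * counts.n2 / counts.n1,
            100.0 * counts.n3 / counts.n2,
            100.0 * counts.n3 / counts.n1,
        )
        per_plant[pid] = accuracy_ratios(counts)
        groups.setdefault(group, []).append(raw)
        tot1 += counts.n1
        tot2 += counts.n2
        tot3 += counts.n3
    group_means = {
        g: tuple(round2(v) for v in np.mean(rows, axis=0)) for g, rows in groups.items()
    }
    overall = accuracy_ratios(CountTriple(tot1, tot2, tot3))
    return {"per_plant": per_plant, "group_means": group_means, "overall": overall,
            "totals": CountTriple(tot1, tot2, tot3)}
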