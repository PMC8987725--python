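"""Per-class plant density from patch-classification tallies.

The density of plant class i over a surveyed area is the fraction of
classified units (patches) assigned to it:

    rho_i = X_i / sum_j X_j

``survey`` turns a stack of unlabeled patches plus any patch classifier
into class tallies; ``density`` converts tallies into a report whose
display percentages are rounded half-up to two decimals (the convention
that reproduces the reference farmland tables digit for digit);
``compare_report`` gives per-class absolute deviations in percentage
points between a predicted report and a ground truth.
"""

from __future__ import annotations

import dataclasses
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from .synthetic import CLASS_NAMES

__all__ = ["ClassCounts", "DensityReport", "density", "survey",
           "compare_report", "format_report"]


@dataclasses.dataclass(frozen=True)
class ClassCounts:
    """Non-negative per-class tallies of classified units."""

    counts: tuple[int, ...]
    names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self):
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if len(self.counts) != len(self.names):
            raise ValueError("one count per class name required")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return int(sum(self.counts))


def _percent_half_up(count: int, total: int) -> float:
    """Exact-rational percentage, rounded half-up to 2 decimals."""
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclasses.dataclass(frozen=True)
class DensityReport:
    """Raw per-class fractions plus display percentages (2 decimals)."""

    fractions: tuple[float, ...]
    percentages: tuple[float, ...]
    total: int
    names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1 within 1e-12")


def density(counts: ClassCounts) -> DensityReport:
    """Per-class density fractions rho_i = X_i / total.

    Raises on an all-zero tally.  Fractions are exact ratios (they sum to 1
    within 1e-12); the display percentages are rounded half-up.
    """
    total = counts.total
    if total == 0:
        raise ValueError("cannot compute densities from all-zero counts")
    fractions = tuple(c / total for c in counts.counts)
    percentages = tuple(_percent_half_up(c, total) for c in counts.counts)
    return DensityReport(fractions=fractions, percentages=percentages,
                         total=total, names=counts.names)


def survey(patches: np.ndarray, classifier,
           names: tuple[str, ...] = CLASS_NAMES) -> ClassCounts:
    """Classify every patch and tally the predictions.

    ``classifier`` is anything with ``predict(patches) -> class indices``
    (a transfer model, a fitted baseline, an adapted meta-model wrapper).
    The tallies always sum to the number of patches.
    """
    patches = np.asarray(patches)
    if len(patches) == 0:
        raise ValueError("no patches to survey")
    pred = np.asarray(classifier.predict(patches))
    tally = np.bincount(pred, minlength=len(names))
    if tally.size > len(names):
        raise ValueError("classifier predicted an out-of-range class index")
    return ClassCounts(counts=tuple(int(c) for c in tally), names=names)


def compare_report(predicted: DensityReport, truth: ClassCounts | DensityReport):
    """Per-class absolute deviation between predicted and true densities,
    in percentage points; returns (deviations array, max deviation)."""
    truth_report = density(truth) if isinstance(truth, ClassCounts) else truth
    if predicted.names != truth_report.names:
        raise ValueError("class sets differ between reports")
    dev = np.abs(np.asarray(predicted.percentages) -
                 np.asarray(truth_report.percentages))
    return dev, float(dev.max())


def format_report(report: DensityReport, blank_zeros: bool = True) -> str:
    """Aligned text table; classes absent from the survey print blank (or
    0.00% with ``blank_zeros=False``)."""
    width = max(len(n) for n in report.names)
    lines = []
    for name, pct in zip(report.names, report.percentages):
        cell = "" if (blank_zeros and pct == 0) else f"{pct:.2f}%"
        lines.append(f"{name:<{width}}  {cell}")
    lines.append(f"{'total units':<{width}}  {report.total}")
    return "\n".join(lines)
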