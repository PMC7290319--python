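"""Duct summaries, inter-duct difference series, and transition reporting.

The core quantity is the normalized inter-duct difference of a metric on
one slice,

    dif(x_i, x_j) = |x_i - x_j| / max(x_i, x_j)  in [0, 1],

computed per slice for a duct pair (e.g. true vs false) and a quantity
(brightness B_AV, Feret or hydraulic diameter).  The raw signed
difference ``x_i - x_j`` in native units is kept alongside.  Cross-patient
gaps compare per-patient duct brightness means via |mean_i - mean_j|,
summarized as mean ± sample SD over patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geometry import CrossSectionMetrics
from .segmentation import DuctLabeling


@dataclass(frozen=True)
class SummaryStat:
    """mean ± sample SD (ddof=1) of n values; sd is 0 when n == 1."""

    mean: float
    sd: float
    n: int
    units: str = ""

    def __str__(self) -> str:
        return f"{self.mean:.2f} ± {self.sd:.2f} (n={self.n})"


@dataclass
class DiffSeries:
    """Per-slice normalized differences of one quantity between two ducts."""

    slice_indices: list[int]
    values: list[float]  # |x_i - x_j| / max(x_i, x_j), dimensionless
    raw: list[float]  # x_i - x_j, native units
    pair: tuple[str, str]
    quantity: str


@dataclass(frozen=True)
class TransitionEvent:
    """A split or merge of the lumen, with the adjacent-slice brightness."""

    slice_index: int
    kind: str  # "split" | "merge"
    brightness_before: dict[str, float]  # duct -> B_AV on the slice before
    brightness_after: dict[str, float]  # duct -> B_AV on the first new slice


def summarize(values: np.ndarray, units: str = "") -> SummaryStat:
    n = int(values.size)
    if n == 0:
        raise ValueError("cannot summarize an empty series")
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    return SummaryStat(mean=float(values.mean()), sd=sd, n=n, units=units)


def duct_summary(series: Sequence[CrossSectionMetrics], field_name: str,
                 units: str = "") -> SummaryStat:
    """mean ± SD of one metric field over a duct's slices (empties skipped)."""
    values = np.array(
        [getattr(m, field_name) for m in series if not m.is_empty], dtype=float
    )
    if values.size == 0:
        raise ValueError(f"no non-empty values of {field_name!r} in series")
    return summarize(values, units)


def _by_slice(series: Sequence[CrossSectionMetrics]) -> dict[int, CrossSectionMetrics]:
    return {m.slice_index: m for m in series if not m.is_empty}


def normalized_difference(x_i: float, x_j: float) -> float:
    """|x_i - x_j| / max(x_i, x_j); 0 when both are 0."""
    m = max(x_i, x_j)
    if m <= 0:
        return 0.0
    return abs(x_i - x_j) / m


def diff_series(series_i: Sequence[CrossSectionMetrics],
                series_j: Sequence[CrossSectionMetrics],
                quantity: str) -> DiffSeries:
    """Normalized per-slice difference of ``quantity`` between two ducts.

    ``quantity`` is a CrossSectionMetrics field ("B_AV", "D_F", "D_Hy", ...).
    Defined only on slices where both ducts exist; no overlap is an error.
    """
    bi, bj = _by_slice(series_i), _by_slice(series_j)
    common = sorted(set(bi) & set(bj))
    if not common:
        raise ValueError("the two series share no slices")
    pair = (series_i[0].duct, series_j[0].duct)
    values, raw = [], []
    for k in common:
        x_i = float(getattr(bi[k], quantity))
        x_j = float(getattr(bj[k], quantity))
        values.append(normalized_difference(x_i, x_j))
        raw.append(x_i - x_j)
    return DiffSeries(common, values, raw, pair, quantity)


def diff_summary(series: DiffSeries) -> SummaryStat:
    """mean ± sample SD of the per-slice normalized differences."""
    return summarize(np.asarray(series.values, dtype=float), units="-")


def pairwise_duct_gap(per_patient_means: Mapping[str, Mapping[str, float]],
                      pair: tuple[str, str]) -> SummaryStat:
    """Cross-patient gap between two ducts' brightness means.

    For each patient, |mean_i - mean_j| in pixels; summarized as
    mean ± sample SD (n-1) over patients.  Symmetric in the pair and
    invariant to patient order.
    """
    duct_i, duct_j = pair
    if len(per_patient_means) < 2:
        raise ValueError("need at least 2 patients")
    gaps = []
    for patient in sorted(per_patient_means):
        means = per_patient_means[patient]
        for duct in pair:
            if duct not in means or means[duct] is None:
                raise ValueError(f"patient {patient!r} lacks a {duct!r} duct mean")
        gaps.append(abs(float(means[duct_i]) - float(means[duct_j])))
    return summarize(np.asarray(gaps), units="pixel")


def detect_transitions(labeling: DuctLabeling,
                       series_by_duct: Mapping[str, Sequence[CrossSectionMetrics]],
                       ) -> list[TransitionEvent]:
    """Annotate each split/merge with the per-duct B_AV on the adjacent slices.

    ``series_by_duct`` is the output of :func:`lumenquant.geometry.measure_series`.
    A split has the common duct before and both lumens after; a merge the
    reverse.  Returns an empty list for an undissected stack.
    """
    by_duct = {d: _by_slice(s) for d, s in series_by_duct.items()}

    def _brightness_at(k: int) -> dict[str, float]:
        out = {}
        for duct, by_slice in by_duct.items():
            if k in by_slice:
                out[duct] = by_slice[k].B_AV
        return out

    events = []
    for tr in sorted(labeling.transitions, key=lambda t: t.slice_index):
        events.append(
            TransitionEvent(
                slice_index=tr.slice_index,
                kind=tr.kind,
                brightness_before=_brightness_at(tr.slice_index - 1),
                brightness_after=_brightness_at(tr.slice_index),
            )
        )
    return events
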