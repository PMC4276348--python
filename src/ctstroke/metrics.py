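"""Detection metrics and segmentation-consistency errors.

Confusion metrics follow the usual definitions on TPN/FPN/TNN/FNN counts:
specificity = TNN/(TNN+FPN), precision = TPN/(TPN+FPN), detection rate
(sensitivity) DR = TPN/(TPN+FNN), correct-classification rate (accuracy)
CR = (TPN+TNN)/total, all reported as percentages.  The false-alarm rate is
FAR = FPN/(FPN+TNN) = 1 - specificity by default; the variant
FPN/(TNN+FNN), which appears in some write-ups, is available behind
``far_denominator="tnn_fnn"``.

Segmentation agreement uses the Martin consistency errors: with R(S, p) the
region of segmentation S containing pixel p, the directional local error is
E(A, B, p) = |R(A,p) \\ R(B,p)| / |R(A,p)|.  GCE takes the better of the two
directional means (tolerant of one map refining the other); LCE picks the
better direction per pixel, so LCE <= GCE always.  The object-level
consistency error (OCE) compares segments as objects, weighting Jaccard
overlaps by intersection-area fractions and each reference object by its
area share, and takes the better direction; unlike GCE it penalises both
over- and under-segmentation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .errors import InputError


@dataclass(frozen=True)
class ConfusionCounts:
    tpn: int
    fpn: int
    tnn: int
    fnn: int

    def __post_init__(self):
        if min(self.tpn, self.fpn, self.tnn, self.fnn) < 0:
            raise InputError("confusion counts must be non-negative")
        if self.total == 0:
            raise InputError("confusion counts must not all be zero")

    @property
    def total(self) -> int:
        return self.tpn + self.fpn + self.tnn + self.fnn


@dataclass(frozen=True)
class MetricReport:
    """Percentages; a metric with a zero denominator is ``None``."""

    specificity: float | None
    precision: float | None
    dr: float | None
    far: float | None
    cr: float | None

    def to_dict(self) -> dict:
        return {"specificity": self.specificity, "precision": self.precision,
                "DR": self.dr, "FAR": self.far, "CR": self.cr}


def _ratio(num: int, den: int) -> float | None:
    return 100.0 * num / den if den else None


def confusion_metrics(c: ConfusionCounts,
                      far_denominator: str = "fpn_tnn") -> MetricReport:
    """Five performance percentages from the confusion counts."""
    if far_denominator == "fpn_tnn":
        far = _ratio(c.fpn, c.fpn + c.tnn)
    elif far_denominator == "tnn_fnn":
        far = _ratio(c.fpn, c.tnn + c.fnn)
    else:
        raise InputError("far_denominator must be 'fpn_tnn' or 'tnn_fnn'")
    return MetricReport(
        specificity=_ratio(c.tnn, c.tnn + c.fpn),
        precision=_ratio(c.tpn, c.tpn + c.fpn),
        dr=_ratio(c.tpn, c.tpn + c.fnn),
        far=far,
        cr=_ratio(c.tpn + c.tnn, c.total),
    )


def read_side_records(path) -> list[tuple[str, str]]:
    """Read a CSV of (predicted, actual) label pairs.

    The file needs a header containing columns named ``predicted`` and
    ``actual`` (case-insensitive).  Malformed rows raise with their line
    number.
    """
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise InputError(f"{path}: empty records file") from None
        cols = [h.strip().lower() for h in header]
        try:
            pi, ai = cols.index("predicted"), cols.index("actual")
        except ValueError:
            raise InputError(
                f"{path}: header must contain 'predicted' and 'actual' columns")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            if len(row) <= max(pi, ai):
                raise InputError(f"{path}: line {lineno}: too few fields")
            records.append((row[pi].strip(), row[ai].strip()))
    if not records:
        raise InputError(f"{path}: no records found")
    return records


def counts_from_records(records, positive: str) -> ConfusionCounts:
    """Accumulate confusion counts, treating ``positive`` as the positive label."""
    tpn = fpn = tnn = fnn = 0
    for predicted, actual in records:
        if actual == positive:
            if predicted == positive:
                tpn += 1
            else:
                fnn += 1
        else:
            if predicted == positive:
                fpn += 1
            else:
                tnn += 1
    return ConfusionCounts(tpn=tpn, fpn=fpn, tnn=tnn, fnn=fnn)


@dataclass(frozen=True)
class ConsistencyReport:
    lce: float
    gce: float
    oce: float

    def to_dict(self) -> dict:
        return {"LCE": self.lce, "GCE": self.gce, "OCE": self.oce}


def _contingency(a: np.ndarray, b: np.ndarray):
    ids_a, inv_a = np.unique(a, return_inverse=True)
    ids_b, inv_b = np.unique(b, return_inverse=True)
    table = np.zeros((ids_a.size, ids_b.size), dtype=np.int64)
    np.add.at(table, (inv_a, inv_b), 1)
    return table


def consistency_errors(seg_a: np.ndarray, seg_b: np.ndarray,
                       support: np.ndarray | None = None) -> ConsistencyReport:
    """LCE, GCE and OCE between two label maps over a common support.

    ``support`` defaults to the pixels labeled non-zero in both maps; it
    must be non-empty and both maps must share a shape.
    """
    seg_a = np.asarray(seg_a)
    seg_b = np.asarray(seg_b)
    if seg_a.shape != seg_b.shape:
        raise InputError("segmentations must share a shape")
    if support is None:
        support = (seg_a != 0) & (seg_b != 0)
    support = np.asarray(support, bool)
    if not support.any():
        raise InputError("empty common support")
    a = seg_a[support].ravel()
    b = seg_b[support].ravel()
    n = a.size

    table = _contingency(a, b)          # n_ij = |A_i ∩ B_j|
    sizes_a = table.sum(axis=1)
    sizes_b = table.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        e_ab = (sizes_a[:, None] - table) / sizes_a[:, None]   # E(A,B,p) per cell
        e_ba = (sizes_b[None, :] - table) / sizes_b[None, :]
    w = table / n
    mean_ab = float((w * e_ab).sum())
    mean_ba = float((w * e_ba).sum())
    lce = float((w * np.minimum(e_ab, e_ba)).sum())
    gce = min(mean_ab, mean_ba)

    oce = min(_oce_directional(table, sizes_a, sizes_b),
              _oce_directional(table.T, sizes_b, sizes_a))
    return ConsistencyReport(lce=lce, gce=gce, oce=oce)


def _oce_directional(table: np.ndarray, sizes_g: np.ndarray,
                     sizes_s: np.ndarray) -> float:
    """Directional object-level error, ground-truth objects along axis 0.

    For each reference object A_j: the candidate objects B_i that intersect
    it are weighted by their area share among all intersecting candidates,
    their Jaccard overlaps |A∩B|/|A∪B| are accumulated, and the deficit from
    1 is weighted by |A_j| / sum |A_l|.
    """
    total = sizes_g.sum()
    err = 0.0
    for j in range(table.shape[0]):
        inter = table[j]
        hit = inter > 0
        if not hit.any():
            err += sizes_g[j] / total
            continue
        w_i = sizes_s[hit] / sizes_s[hit].sum()
        union = sizes_g[j] + sizes_s[hit] - inter[hit]
        overlap = float(np.sum((inter[hit] / union) * w_i))
        err += (1.0 - overlap) * sizes_g[j] / total
    return float(err)
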