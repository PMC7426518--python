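"""Histogram, gray-level co-occurrence and gray-level run-length features.

Ten features are computed per quantized ROI:

========  =================================================================
SKE, KUR  histogram skewness and (non-excess) kurtosis of the inside-mask
          gray levels — a normal distribution gives KUR ~ 3
CON       GLCM contrast,  sum (i-j)^2 p(i,j)
ENE       GLCM energy (angular second moment),  sum p(i,j)^2
ENT       GLCM entropy,  -sum p log2 p
INC       GLCM information measure of correlation 1,
          (HXY - HXY1) / max(HX, HY)
LRE       long-run emphasis,  sum j^2 r(i,j) / Nr
RLN       run-length non-uniformity,  sum_j (sum_i r(i,j))^2 / Nr
LGLRE     low gray-level run emphasis,  sum r(i,j) / i^2 / Nr
SRLGLE    short-run low gray-level emphasis,  sum r(i,j) / (i^2 j^2) / Nr
========  =================================================================

GLCMs use distance 1 and the four angles 0, 45, 90 and 135 degrees, with
symmetric accumulation (each ordered pair counted in both orders, so 0
and 180 degrees coincide).  GRLMs count maximal constant-level runs along
the same four directions; outside-mask pixels break runs.  Each
second-order feature is the mean over the (non-empty) four directions.
In the run-length weights the gray index ``i`` is 1-based (``level + 1``)
so that level 0 does not divide by zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from texturestager.image_io import ROISample
from texturestager.preprocess import OUTSIDE, QuantizedROI, normalize_quantize

#: (delta_row, delta_col) offsets for the four angles at distance 1.
ANGLE_OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}

ANGLES = tuple(ANGLE_OFFSETS)

FEATURE_NAMES = ("SKE", "KUR", "CON", "ENE", "ENT", "INC", "LRE", "RLN", "LGLRE", "SRLGLE")

GLCM_FEATURES = ("CON", "ENE", "ENT", "INC")
GRLM_FEATURES = ("LRE", "RLN", "LGLRE", "SRLGLE")


class ConstantROIError(ValueError):
    """Raised when a feature is undefined on a constant (zero-variance) ROI."""


@dataclass
class CooccurrenceMatrix:
    """Symmetric gray-level co-occurrence counts for one offset."""

    counts: np.ndarray = field(repr=False)
    offset: tuple[int, int]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def is_empty(self) -> bool:
        return self.total == 0

    @property
    def probabilities(self) -> np.ndarray:
        """Counts normalized to sum 1 (requires at least one pair)."""
        t = self.total
        if t == 0:
            raise ValueError("empty co-occurrence matrix has no probabilities")
        return self.counts / t


@dataclass
class RunLengthMatrix:
    """Gray-level run-length counts ``r(level, run_length)`` for one angle.

    Rows index the gray level (0-based storage; the weighting formulas use
    the 1-based index ``level + 1``), columns index the run length starting
    at 1 (column ``j - 1`` holds runs of length ``j``).
    """

    counts: np.ndarray = field(repr=False)
    angle: int

    @property
    def n_runs(self) -> int:
        return int(self.counts.sum())


def glcm(roi: QuantizedROI, offset: tuple[int, int]) -> CooccurrenceMatrix:
    """Co-occurrence counts at ``offset``; both pixels must be in the mask.

    Each unordered neighbor pair contributes to ``counts[i, j]`` and
    ``counts[j, i]``, making the matrix symmetric.
    """
    if tuple(offset) not in ANGLE_OFFSETS.values():
        raise ValueError(f"offset {offset} is not one of the four distance-1 offsets")
    dr, dc = offset
    lv, mask = roi.levels, roi.mask
    h, w = lv.shape
    r0, r1 = max(0, -dr), h - max(0, dr)
    c0, c1 = max(0, -dc), w - max(0, dc)
    src = lv[r0:r1, c0:c1]
    dst = lv[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    i, j = src[valid], dst[valid]
    counts = np.zeros((roi.n_levels, roi.n_levels), dtype=np.int64)
    np.add.at(counts, (i, j), 1)
    np.add.at(counts, (j, i), 1)
    return CooccurrenceMatrix(counts=counts, offset=(dr, dc))


def glcm_features(
    m: CooccurrenceMatrix, base: float = 2.0, inc_variant: str = "imc1"
) -> dict[str, float]:
    """Contrast, energy, entropy and information correlation of one GLCM.

    ``base`` sets the logarithm base for the entropy terms.  ``inc_variant``
    selects the information measure of correlation: ``"imc1"`` (default)
    is ``(HXY - HXY1) / max(HX, HY)``; ``"imc2"`` is
    ``sqrt(1 - exp(-2 (HXY2 - HXY)))``.  Degenerate marginals (zero
    entropy) give INC = 0.
    """
    if m.is_empty:
        raise ValueError("cannot compute features of an empty co-occurrence matrix")
    p = m.probabilities
    nz = p > 0
    pnz = p[nz]
    log = lambda x: np.log(x) / math.log(base)

    idx = np.arange(p.shape[0], dtype=np.float64)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    con = float(np.sum((ii - jj) ** 2 * p))
    ene = float(np.sum(p**2))
    hxy = float(-np.sum(pnz * log(pnz)))

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    hx = float(-np.sum(px[px > 0] * log(px[px > 0])))
    hy = float(-np.sum(py[py > 0] * log(py[py > 0])))
    outer = np.outer(px, py)
    if inc_variant == "imc1":
        # HXY1 sums over the cells where p(i,j) > 0 (0 log 0 := 0)
        hxy1 = float(-np.sum(p[nz] * log(outer[nz])))
        denom = max(hx, hy)
        inc = (hxy - hxy1) / denom if denom > 0 else 0.0
    elif inc_variant == "imc2":
        onz = outer > 0
        hxy2 = float(-np.sum(outer[onz] * log(outer[onz])))
        arg = 1.0 - math.exp(-2.0 * max(hxy2 - hxy, 0.0))
        inc = math.sqrt(max(arg, 0.0))
    else:
        raise ValueError(f"unknown inc_variant {inc_variant!r}")
    return {"CON": con, "ENE": ene, "ENT": hxy, "INC": float(inc)}


def _direction_lines(levels: np.ndarray, angle: int) -> list[np.ndarray]:
    """The maximal pixel lines of the grid along one of the four angles."""
    h, w = levels.shape
    if angle == 0:
        return list(levels)
    if angle == 90:
        return list(levels.T)
    if angle == 45:  # anti-diagonals (constant row + col)
        a = np.fliplr(levels)
    elif angle == 135:  # main diagonals (constant row - col)
        a = levels
    else:
        raise ValueError(f"angle {angle} is not one of {ANGLES}")
    return [np.diagonal(a, k).copy() for k in range(-(h - 1), w)]


def grlm(roi: QuantizedROI, angle: int) -> RunLengthMatrix:
    """Run-length counts along ``angle``; outside-mask pixels break runs."""
    levels = roi.levels
    max_run = max(levels.shape)
    counts = np.zeros((roi.n_levels, max_run), dtype=np.int64)
    for line in _direction_lines(levels, angle):
        if line.size == 0:
            continue
        # segment boundaries wherever the value changes
        change = np.flatnonzero(np.diff(line) != 0) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [line.size]))
        for s, e in zip(starts, ends):
            lvl = line[s]
            if lvl != OUTSIDE:
                counts[lvl, e - s - 1] += 1
    return RunLengthMatrix(counts=counts, angle=angle)


def grlm_features(m: RunLengthMatrix) -> dict[str, float]:
    """Galloway run-emphasis features of one run-length matrix."""
    nr = m.n_runs
    if nr == 0:
        raise ValueError("run-length matrix contains no runs")
    counts = m.counts
    gray = np.arange(1, counts.shape[0] + 1, dtype=np.float64)  # 1-based index
    length = np.arange(1, counts.shape[1] + 1, dtype=np.float64)
    lre = float(np.sum(counts * length**2) / nr)
    rln = float(np.sum(counts.sum(axis=0) ** 2) / nr)
    lglre = float(np.sum(counts / gray[:, None] ** 2) / nr)
    srlgle = float(np.sum(counts / (gray[:, None] ** 2 * length[None, :] ** 2)) / nr)
    return {"LRE": lre, "RLN": rln, "LGLRE": lglre, "SRLGLE": srlgle}


def histogram_features(roi: QuantizedROI) -> dict[str, float]:
    """Skewness and non-excess kurtosis of the inside-mask gray levels.

    Central moments use population denominators: SKE = m3 / m2^(3/2),
    KUR = m4 / m2^2.  Undefined (raises) on a constant ROI.
    """
    x = roi.inside_levels.astype(np.float64)
    if x.size < 3:
        raise ValueError("histogram features need >= 3 inside-mask pixels")
    c = x - x.mean()
    m2 = float(np.mean(c**2))
    if m2 == 0.0:
        raise ConstantROIError("undefined histogram moments: constant ROI")
    m3 = float(np.mean(c**3))
    m4 = float(np.mean(c**4))
    return {"SKE": m3 / m2**1.5, "KUR": m4 / m2**2}


@dataclass
class FeatureVector:
    """The ten texture features of one ROI.

    Second-order entries are means over the non-empty directions; SKE and
    KUR are NaN when undefined (constant ROI).
    """

    SKE: float
    KUR: float
    CON: float
    ENE: float
    ENT: float
    INC: float
    LRE: float
    RLN: float
    LGLRE: float
    SRLGLE: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def extract_features(
    roi: QuantizedROI, base: float = 2.0, inc_variant: str = "imc1"
) -> FeatureVector:
    """All ten features of one quantized ROI.

    GLCM and GRLM features are computed per direction and averaged over
    the directions that contain at least one pair / run (directions with
    no valid pair — possible on thin masks — are dropped from the mean,
    not zero-filled).  A constant ROI leaves SKE/KUR as NaN but the
    second-order families defined.
    """
    try:
        hist = histogram_features(roi)
    except ValueError:  # constant ROI or too few pixels: histogram undefined
        hist = {"SKE": math.nan, "KUR": math.nan}

    glcm_acc: dict[str, list[float]] = {k: [] for k in GLCM_FEATURES}
    for offset in ANGLE_OFFSETS.values():
        m = glcm(roi, offset)
        if m.is_empty:
            continue
        for k, v in glcm_features(m, base=base, inc_variant=inc_variant).items():
            glcm_acc[k].append(v)
    if not glcm_acc["ENE"]:
        raise ValueError("no direction contains a valid pixel pair (mask too small)")

    grlm_acc: dict[str, list[float]] = {k: [] for k in GRLM_FEATURES}
    for angle in ANGLES:
        m = grlm(roi, angle)
        if m.n_runs == 0:
            continue
        for k, v in grlm_features(m).items():
            grlm_acc[k].append(v)

    values = dict(hist)
    values.update({k: float(np.mean(v)) for k, v in glcm_acc.items()})
    values.update({k: float(np.mean(v)) for k, v in grlm_acc.items()})
    return FeatureVector(**values)


def compute_feature_table(
    samples: list[ROISample],
    n_levels: int = 256,
    reader: int = 1,
    base: float = 2.0,
    inc_variant: str = "imc1",
) -> pd.DataFrame:
    """Feature table for one reader: subjects x ``<sequence>_<FEATURE>``.

    Each subject contributes one row with ten features per sequence.
    """
    rows: dict[str, dict] = {}
    for s in samples:
        if s.reader != reader:
            continue
        roi = normalize_quantize(s, n_levels=n_levels)
        fv = extract_features(roi, base=base, inc_variant=inc_variant)
        row = rows.setdefault(
            s.subject_id, {"subject_id": s.subject_id, "class_label": s.class_label}
        )
        for name, value in fv.as_dict().items():
            row[f"{s.sequence}_{name}"] = value
    if not rows:
        raise ValueError(f"no samples for reader {reader}")
    df = pd.DataFrame(list(rows.values()))
    lead = ["subject_id", "class_label"]
    return df[lead + sorted(c for c in df.columns if c not in lead)]
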