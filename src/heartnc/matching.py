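"""Thorax measurements and reference/test subject matching.

A test subject is paired with the same-group reference whose measurement
triple (W1, W2, L) lies closest in root-sum-of-squared-differences (the
LSD score).  Ties are broken by lexicographic reference id so matching is
deterministic; one reference may serve several tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MeasurementError, NoCandidateError, ParameterError
from .projection import DRRImage

__all__ = ["ThoraxMeasurements", "MatchResult", "measure_thorax", "lsd", "select_matches"]


@dataclass(frozen=True)
class ThoraxMeasurements:
    """W1/W2: inner-rib gaps at the upper/lower rows; L: row separation (cm)."""

    W1: float
    W2: float
    L: float
    group_label: str = ""
    subject_id: str = ""

    def __post_init__(self):
        if min(self.W1, self.W2, self.L) <= 0:
            raise ParameterError(
                f"thorax measurements must be positive, got "
                f"({self.W1}, {self.W2}, {self.L})"
            )

    def triple(self) -> np.ndarray:
        return np.array([self.W1, self.W2, self.L], dtype=float)


@dataclass
class MatchResult:
    pairs: list = field(default_factory=list)  # (test_id, ref_id, lsd)
    candidate_scores: pd.DataFrame | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "pairs": [
                    {"test_id": t, "ref_id": r, "lsd": s} for t, r, s in self.pairs
                ]
            },
            indent=1,
        )

    def write(self, path_csv, path_json=None):
        df = pd.DataFrame(self.pairs, columns=["test_id", "ref_id", "lsd"])
        df.to_csv(path_csv, index=False)
        if path_json:
            Path(path_json).write_text(self.to_json())


def _inner_edges(drr: DRRImage, row_y: float, midline_x: float,
                 exclusion_cm: float, rel_threshold: float):
    """Innermost high-gradient columns flanking the midline on one row."""
    row = int(round(float(drr.row_of_y(row_y))))
    if row < 0 or row >= drr.shape[0]:
        raise MeasurementError(f"row y={row_y} cm lies outside the image")
    profile = drr.pixels[row, :]
    grad = np.abs(np.gradient(profile))
    x = drr.x_of_col(np.arange(drr.shape[1]))
    valid = np.abs(x - midline_x) > exclusion_cm
    if not valid.any() or grad[valid].max() <= 0:
        raise MeasurementError(f"no intensity structure on row y={row_y} cm")
    thr = rel_threshold * grad[valid].max()
    strong = valid & (grad >= thr)
    left = strong & (x < midline_x)
    right = strong & (x > midline_x)
    if not left.any() or not right.any():
        raise MeasurementError(
            f"no flanking rib edges found on row y={row_y} cm"
        )

    def cluster_mean(side_mask, innermost_idx, step):
        # sub-pixel border: average the contiguous above-threshold run
        idxs = [innermost_idx]
        i = innermost_idx + step
        while 0 <= i < len(side_mask) and side_mask[i]:
            idxs.append(i)
            i += step
        return float(x[idxs].mean())

    xl = cluster_mean(left, int(np.nonzero(left)[0].max()), -1)
    xr = cluster_mean(right, int(np.nonzero(right)[0].min()), +1)
    return xl, xr


def measure_thorax(
    drr: DRRImage,
    upper_row_y: float,
    lower_row_y: float,
    midline_x: float | None = None,
    exclusion_cm: float = 3.0,
    rel_threshold: float = 0.5,
    group_label: str = "",
    subject_id: str = "",
) -> ThoraxMeasurements:
    """Measure (W1, W2, L) on a radiograph at two user-chosen row heights.

    The vertebral row levels are manual anatomy identifications, so the two
    row y-coordinates are inputs.  On each row the width is the distance
    between the two innermost high-gradient columns flanking the midline;
    a central exclusion zone keeps the spine from masquerading as a rib
    border.
    """
    if not lower_row_y > upper_row_y:
        raise MeasurementError(
            f"lower row ({lower_row_y}) must lie inferior to upper row ({upper_row_y})"
        )
    if midline_x is None:
        if drr.isocenter_px is not None:
            midline_x = float(drr.x_of_col(drr.isocenter_px[0]))
        else:
            midline_x = float(drr.x_of_col((drr.shape[1] - 1) / 2.0))
    xl1, xr1 = _inner_edges(drr, upper_row_y, midline_x, exclusion_cm, rel_threshold)
    xl2, xr2 = _inner_edges(drr, lower_row_y, midline_x, exclusion_cm, rel_threshold)
    return ThoraxMeasurements(
        W1=xr1 - xl1,
        W2=xr2 - xl2,
        L=lower_row_y - upper_row_y,
        group_label=group_label,
        subject_id=subject_id,
    )


def lsd(ref: ThoraxMeasurements, test: ThoraxMeasurements) -> float:
    """Root-sum-of-squared-differences of the two measurement triples (cm)."""
    d = test.triple() - ref.triple()
    return float(np.sqrt(np.dot(d, d)))


def select_matches(refs, tests) -> MatchResult:
    """Pair each test with the lowest-scoring same-group reference."""
    refs = list(refs)
    tests = list(tests)
    rows = []
    pairs = []
    for t in tests:
        candidates = [r for r in refs if r.group_label == t.group_label]
        if not candidates:
            raise NoCandidateError(
                f"no reference candidates in group {t.group_label!r} "
                f"for test {t.subject_id!r}"
            )
        scored = sorted(
            ((lsd(r, t), r.subject_id) for r in candidates),
            key=lambda sr: (sr[0], sr[1]),
        )
        for score, rid in scored:
            rows.append(
                {"test_id": t.subject_id, "ref_id": rid,
                 "group": t.group_label, "lsd": score}
            )
        best_score, best_id = scored[0]
        pairs.append((t.subject_id, best_id, best_score))
    return MatchResult(pairs=pairs, candidate_scores=pd.DataFrame(rows))


def read_measurements_csv(path):
    """CSV with columns subject_id, group, W1, W2, L."""
    df = pd.read_csv(path)
    return [
        ThoraxMeasurements(
            W1=row.W1, W2=row.W2, L=row.L,
            group_label=str(row.group), subject_id=str(row.subject_id),
        )
        for row in df.itertuples()
    ]


def write_measurements_csv(measurements, path):
    pd.DataFrame(
        [
            {"subject_id": m.subject_id, "group": m.group_label,
             "W1": m.W1, "W2": m.W2, "L": m.L}
            for m in measurements
        ]
    ).to_csv(path, index=False)
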