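"""Functional connectivity matrices, ROI time series and atlas tables.

Correlation matrices are kept raw (no Fisher transform); thresholding
downstream operates directly on Pearson values.  ROI ordering is taken
from the atlas and enforced on every matrix — mismatches are errors,
never silently reordered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError

#: symmetry tolerance accepted when reading matrices from text files;
#: after passing, the matrix is symmetrized (average with its transpose).
FILE_SYMMETRY_TOL = 1e-8

#: strict symmetry tolerance for in-memory matrices.
SYMMETRY_TOL = 1e-12

RSN_LABELS = (
    "Vis",
    "SomMot",
    "DorsAttn",
    "SalVentAttn",
    "Limbic",
    "Cont",
    "Default",
)


@dataclass
class ROITimeSeries:
    """Per-subject ROI x timepoint array.

    Requires at least two timepoints and strictly positive variance in
    every ROI series; constant series cannot be correlated.
    """

    subject_id: str
    values: np.ndarray
    roi_ids: list[int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputError("time series array must be 2-D (ROI x timepoint)")
        n_roi, n_tp = self.values.shape
        if n_tp < 2:
            raise InputError(f"need >= 2 timepoints, got {n_tp}")
        if len(self.roi_ids) != n_roi:
            raise InputError(
                f"roi_ids length {len(self.roi_ids)} != number of rows {n_roi}"
            )
        if not np.isfinite(self.values).all():
            raise InputError("time series contains non-finite values")
        sd = self.values.std(axis=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise InputError(
                f"constant time series for ROI {self.roi_ids[bad[0]]}"
            )


@dataclass
class FCMatrix:
    """One subject's symmetric ROI x ROI correlation matrix, unit diagonal."""

    subject_id: str
    matrix: np.ndarray
    roi_ids: list[int]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        validate_fc_array(self.matrix, self.roi_ids)

    @property
    def n_rois(self) -> int:
        return self.matrix.shape[0]


def validate_fc_array(
    matrix: np.ndarray, roi_ids: list[int], sym_tol: float = SYMMETRY_TOL
) -> None:
    """Check square/symmetric/unit-diagonal/range invariants of an FC array."""
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValidationError(f"FC matrix must be square, got shape {matrix.shape}")
    n = matrix.shape[0]
    if len(roi_ids) != n:
        raise ValidationError(f"roi_ids length {len(roi_ids)} != matrix size {n}")
    if len(set(roi_ids)) != n:
        raise ValidationError("duplicate roi_ids")
    if not np.isfinite(matrix).all():
        raise ValidationError("FC matrix contains non-finite values")
    asym = np.abs(matrix - matrix.T)
    if asym.max(initial=0.0) > sym_tol:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValidationError(
            f"FC matrix asymmetric at ({roi_ids[i]}, {roi_ids[j]}): "
            f"{matrix[i, j]!r} vs {matrix[j, i]!r}"
        )
    if not np.allclose(np.diag(matrix), 1.0, rtol=0, atol=0):
        k = int(np.flatnonzero(np.diag(matrix) != 1.0)[0])
        raise ValidationError(f"diagonal entry for ROI {roi_ids[k]} is not 1")
    off = matrix[~np.eye(n, dtype=bool)]
    if off.size and (off.min() < -1.0 or off.max() > 1.0):
        bad = np.abs(matrix) > 1.0
        np.fill_diagonal(bad, False)
        i, j = map(int, np.argwhere(bad)[0])
        raise ValidationError(
            f"entry ({roi_ids[i]}, {roi_ids[j]}) = {matrix[i, j]} outside [-1, 1]"
        )


@dataclass
class Atlas:
    """ROI lookup table: id, name, resting-state-network label, MNI centroid."""

    roi_ids: list[int]
    names: list[str]
    rsns: list[str]
    centroids: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def __post_init__(self) -> None:
        n = len(self.roi_ids)
        if len(set(self.roi_ids)) != n:
            raise ValidationError("duplicate roi_id in atlas")
        if sorted(self.roi_ids) != list(range(1, n + 1)):
            raise ValidationError("atlas roi_ids must be contiguous 1..n")
        if len(self.names) != n or len(self.rsns) != n:
            raise ValidationError("atlas column lengths differ")
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape != (n, 3):
            raise ValidationError(
                f"centroids must be (n, 3), got {self.centroids.shape}"
            )

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    def rois_in_rsn(self, rsn: str) -> list[int]:
        rois = [r for r, lbl in zip(self.roi_ids, self.rsns) if lbl == rsn]
        if not rois:
            raise InputError(f"unknown RSN label: {rsn!r}")
        return rois

    @property
    def rsn_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for lbl in self.rsns:
            seen.setdefault(lbl)
        return list(seen)


def pearson_fc(ts: ROITimeSeries) -> FCMatrix:
    """Sample Pearson correlation between every pair of ROI series.

    The diagonal is set to exactly 1 and the matrix is symmetrized to
    remove rounding asymmetry from the dot products.
    """
    mat = np.corrcoef(ts.values)
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 1.0)
    np.clip(mat, -1.0, 1.0, out=mat)
    return FCMatrix(ts.subject_id, mat, list(ts.roi_ids))


def write_fc_matrix(fc: FCMatrix, path) -> None:
    """CSV with ROI-id header row and column."""
    df = pd.DataFrame(fc.matrix, index=fc.roi_ids, columns=fc.roi_ids)
    df.to_csv(path, float_format="%.17g")


def read_fc_matrix(path, subject_id: str | None = None) -> FCMatrix:
    """Read a CSV FC matrix written by :func:`write_fc_matrix`.

    Small asymmetry from text rounding (< 1e-8) is absorbed by
    symmetrization; anything larger is rejected.
    """
    df = pd.read_csv(path, index_col=0)
    try:
        roi_ids = [int(c) for c in df.columns]
        row_ids = [int(r) for r in df.index]
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-integer ROI ids in header") from exc
    if roi_ids != row_ids:
        raise ValidationError(f"{path}: header row and column ROI ids differ")
    mat = df.to_numpy(dtype=float)
    validate_fc_array(mat, roi_ids, sym_tol=FILE_SYMMETRY_TOL)
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 1.0)
    if subject_id is None:
        subject_id = _stem(path)
    return FCMatrix(subject_id, mat, roi_ids)


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


def write_atlas(atlas: Atlas, path) -> None:
    df = pd.DataFrame(
        {
            "roi_id": atlas.roi_ids,
            "name": atlas.names,
            "rsn": atlas.rsns,
            "x": atlas.centroids[:, 0],
            "y": atlas.centroids[:, 1],
            "z": atlas.centroids[:, 2],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_atlas(path) -> Atlas:
    df = pd.read_csv(path, sep="\t")
    required = {"roi_id", "name", "rsn", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing atlas columns {sorted(missing)}")
    return Atlas(
        roi_ids=[int(r) for r in df["roi_id"]],
        names=[str(s) for s in df["name"]],
        rsns=[str(s) for s in df["rsn"]],
        centroids=df[["x", "y", "z"]].to_numpy(dtype=float),
    )


def default_atlas() -> Atlas:
    """The packaged 200-ROI, 7-network atlas table."""
    from importlib import resources

    ref = resources.files("netcurv.data") / "schaefer200_7net.tsv"
    with resources.as_file(ref) as p:
        return read_atlas(p)
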