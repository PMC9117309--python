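"""Group statistics: per-density t-tests, nodal AUC comparison, BH-FDR,
partial correlation with covariates, and ROI-set overlap counting.

FDR families follow the reporting structure: for global measures the
correction runs across the densities within each measure; for nodal
measures across the nodes within each measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .graphs import DensityGrid


@dataclass
class MeasureTensor:
    """subject x axis array of one measure, with group labels.

    The axis is either the density grid (global measures) or the ROI ids
    (nodal AUCs).
    """

    subject_ids: list[str]
    axis: list
    values: np.ndarray
    groups: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.axis)):
            raise InputError(
                f"values shape {self.values.shape} != "
                f"({len(self.subject_ids)}, {len(self.axis)})"
            )
        if not np.isfinite(self.values).all():
            raise InputError("measure tensor contains missing values")
        labels = set(self.groups)
        if len(labels) != 2:
            raise InputError(f"need exactly two groups, got {sorted(labels)}")

    def split(self) -> tuple[str, np.ndarray, str, np.ndarray]:
        """Rows split by group, group labels in sorted order."""
        la, lb = sorted(set(self.groups))
        mask = np.array([g == la for g in self.groups])
        return la, self.values[mask], lb, self.values[~mask]


def auc_over_densities(values, grid: DensityGrid) -> float:
    """Trapezoidal integral of a per-density series over the density axis."""
    values = np.asarray(values, dtype=float)
    x = np.asarray(grid.values)
    if values.shape[-1] != len(x):
        raise InputError(
            f"series length {values.shape[-1]} != grid length {len(x)}"
        )
    if len(x) < 2:
        raise InputError("need >= 2 grid points for an AUC")
    return float(np.trapezoid(values, x))


def two_sample_t(group_a, group_b, equal_var: bool = True) -> tuple[float, float]:
    """Two-tailed two-sample t test; pooled variance by default (Welch
    available via ``equal_var=False``)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("both groups need n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise InputError("zero pooled variance: t statistic undefined")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def bh_fdr(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and flags at alpha."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise InputError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def _compare(tensor: MeasureTensor, alpha: float, equal_var: bool) -> pd.DataFrame:
    la, va, lb, vb = tensor.split()
    rows = []
    for k, label in enumerate(tensor.axis):
        t, p = two_sample_t(va[:, k], vb[:, k], equal_var=equal_var)
        rows.append(
            {
                "axis": label,
                f"mean_{la}": va[:, k].mean(),
                f"sd_{la}": va[:, k].std(ddof=1),
                f"mean_{lb}": vb[:, k].mean(),
                f"sd_{lb}": vb[:, k].std(ddof=1),
                "t": t,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adj"], df["significant"] = bh_fdr(df["p"].to_numpy(), alpha)
    return df


def compare_global(
    tensor: MeasureTensor, alpha: float = 0.05, equal_var: bool = True
) -> pd.DataFrame:
    """One t-test per density; BH-FDR across the densities."""
    return _compare(tensor, alpha, equal_var)


def compare_nodal(
    tensor: MeasureTensor, alpha: float = 0.05, equal_var: bool = True
) -> pd.DataFrame:
    """One t-test per node on the per-node AUCs; BH-FDR across the nodes."""
    return _compare(tensor, alpha, equal_var)


def nodal_auc_tensor(
    subject_ids: list[str],
    groups: list[str],
    per_density_values: np.ndarray,
    grid: DensityGrid,
    roi_ids: list,
) -> MeasureTensor:
    """Collapse a subject x density x node array into a subject x node
    tensor of AUCs over the density grid."""
    arr = np.asarray(per_density_values, dtype=float)
    if arr.ndim != 3 or arr.shape[1] != len(grid) or arr.shape[2] != len(roi_ids):
        raise InputError(
            f"expected (n_subjects, {len(grid)}, {len(roi_ids)}), got {arr.shape}"
        )
    x = np.asarray(grid.values)
    aucs = np.trapezoid(arr, x, axis=1)
    return MeasureTensor(subject_ids, list(roi_ids), aucs, groups)


def partial_correlation(x, y, covariates) -> tuple[float, float]:
    """Pearson correlation of x and y after regressing out covariates.

    Both variables are residualized on [1, covariates] by least squares;
    the p-value uses the t distribution with df = n - k - 2, k the
    number of covariate columns.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    n = len(x)
    if len(y) != n or C.shape[0] != n:
        raise InputError("x, y and covariates must have equal length")
    # constant covariate columns are absorbed by the intercept: drop them
    # (so a constant-only covariate reduces to plain Pearson correlation)
    C = C[:, C.std(axis=0) > 0]
    k = C.shape[1]
    if n <= k + 2:
        raise InputError(f"need n > {k + 2} observations, got {n}")
    design = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise InputError("rank-deficient covariate matrix")
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    # a variable explained exactly by the covariates leaves only rounding
    # noise in its residual: the partial correlation is 0 by definition
    for resid, orig in ((rx, x), (ry, y)):
        if resid.std() <= 1e-10 * max(1.0, orig.std()):
            return 0.0, 1.0
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p


def roi_overlap(significant, targets) -> tuple[set, dict[str, int]]:
    """Exact intersection of two ROI sets with counts."""
    sig = set(significant)
    tgt = set(targets)
    inter = sig & tgt
    counts = {
        "n_significant": len(sig),
        "n_targets": len(tgt),
        "n_overlap": len(inter),
    }
    return inter, counts
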