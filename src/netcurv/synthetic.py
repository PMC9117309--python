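"""Two-group synthetic cohorts with planted modular structure.

Cohorts are built from block-constant correlation targets: ROIs are
partitioned into blocks, within-block entries share one mean and
between-block entries another, and group "A" has its within-block mean
reduced by ``group_effect``.  Subject-level jitter is added and the
result is projected to the nearest valid correlation matrix (eigenvalue
clipping at a small positive floor, diagonal renormalization).  When
``n_timepoints`` is set, subjects are realized as multivariate Gaussian
time series whose sample Pearson correlation is the FC matrix.

Randomness uses one global seed with per-subject substreams so that
subjects are independent yet the whole cohort is a pure function of the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .connectivity import Atlas, FCMatrix, ROITimeSeries, RSN_LABELS
from .errors import ConfigurationError, InputError

EIG_FLOOR = 1e-6

# seed-stream tags keeping the independent draw streams apart
_STREAM_MATRIX = 0
_STREAM_DEMOG = 1
_STREAM_SCORE = 2
_STREAM_TERMS = 3


@dataclass(frozen=True)
class CohortSpec:
    n_rois: int
    n_subjects_per_group: int
    n_blocks: int
    within_block_mu: float = 0.6
    between_block_mu: float = 0.1
    group_effect: float = 0.0
    noise_sd: float = 0.0
    n_timepoints: int | None = None
    score_slope: float = 0.0
    score_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        def bad(field: str, why: str):
            return ConfigurationError(f"invalid CohortSpec.{field}: {why}")

        if self.n_rois < 1:
            raise bad("n_rois", f"must be positive, got {self.n_rois}")
        if self.n_subjects_per_group < 1:
            raise bad("n_subjects_per_group", f"got {self.n_subjects_per_group}")
        if not (1 <= self.n_blocks <= self.n_rois):
            raise bad("n_blocks", f"must be in [1, n_rois], got {self.n_blocks}")
        for field in ("within_block_mu", "between_block_mu"):
            v = getattr(self, field)
            if not (-1.0 < v < 1.0):
                raise bad(field, f"must lie in (-1, 1), got {v}")
        if self.group_effect < 0:
            raise bad("group_effect", f"must be >= 0, got {self.group_effect}")
        if not (-1.0 < self.within_block_mu - self.group_effect < 1.0):
            raise bad("group_effect", "pushes within-block mean outside (-1, 1)")
        if self.noise_sd < 0:
            raise bad("noise_sd", f"must be >= 0, got {self.noise_sd}")
        if self.n_timepoints is not None and self.n_timepoints < 2:
            raise bad("n_timepoints", f"must be >= 2, got {self.n_timepoints}")
        if self.score_noise_sd < 0:
            raise bad("score_noise_sd", f"must be >= 0, got {self.score_noise_sd}")

    @property
    def blocks(self) -> list[np.ndarray]:
        return [b for b in np.array_split(np.arange(self.n_rois), self.n_blocks)]

    def block_of(self) -> np.ndarray:
        """Block index of each ROI."""
        lab = np.empty(self.n_rois, dtype=int)
        for k, b in enumerate(self.blocks):
            lab[b] = k
        return lab


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    age: float
    gender: str
    clinical_score: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("A", "B"):
            raise InputError(f"group must be 'A' or 'B', got {self.group!r}")
        if self.gender not in ("F", "M"):
            raise InputError(f"gender must be 'F' or 'M', got {self.gender!r}")
        if self.age <= 0:
            raise InputError(f"age must be positive, got {self.age}")
        if self.clinical_score is not None and self.group != "A":
            raise InputError("clinical_score may be set only for group A")


def _target_matrix(spec: CohortSpec, group: str) -> np.ndarray:
    within = spec.within_block_mu - (spec.group_effect if group == "A" else 0.0)
    lab = spec.block_of()
    same = lab[:, None] == lab[None, :]
    mat = np.where(same, within, spec.between_block_mu)
    np.fill_diagonal(mat, 1.0)
    return mat


def nearest_correlation(mat: np.ndarray, eig_floor: float = EIG_FLOOR) -> np.ndarray:
    """Project a symmetric matrix to a valid correlation matrix.

    Eigenvalues are clipped at ``eig_floor`` and the diagonal is
    renormalized to 1.  Matrices already valid are returned unchanged so
    that noiseless constructions stay exact.
    """
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals[0] >= eig_floor and np.allclose(np.diag(sym), 1.0, atol=0):
        return sym
    vals = np.clip(vals, eig_floor, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    fixed = (fixed + fixed.T) / 2.0
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _subject_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream, index])


def _subject_fc(
    spec: CohortSpec, target: np.ndarray, rng: np.random.Generator, subject_id: str
) -> tuple[FCMatrix, ROITimeSeries | None]:
    n = spec.n_rois
    mat = target.copy()
    if spec.noise_sd > 0:
        jitter = rng.normal(0.0, spec.noise_sd, size=(n, n))
        jitter = (jitter + jitter.T) / 2.0
        np.fill_diagonal(jitter, 0.0)
        mat = np.clip(mat + jitter, -0.999, 0.999)
        np.fill_diagonal(mat, 1.0)
    mat = nearest_correlation(mat)
    roi_ids = list(range(1, n + 1))
    if spec.n_timepoints is None:
        np.clip(mat, -1.0, 1.0, out=mat)
        return FCMatrix(subject_id, mat, roi_ids), None
    chol = np.linalg.cholesky(mat + np.eye(n) * 1e-12)
    series = chol @ rng.standard_normal((n, spec.n_timepoints))
    ts = ROITimeSeries(subject_id, series, roi_ids)
    fc = np.corrcoef(series)
    fc = (fc + fc.T) / 2.0
    np.fill_diagonal(fc, 1.0)
    np.clip(fc, -1.0, 1.0, out=fc)
    return FCMatrix(subject_id, fc, roi_ids), ts


def generate_cohort(
    spec: CohortSpec, with_timeseries: bool = False
):
    """Generate (FC matrices, subject records) for both groups.

    Group A subjects come first.  With ``with_timeseries=True`` (only
    meaningful when ``spec.n_timepoints`` is set) a third list of
    :class:`ROITimeSeries` (or ``None``) is returned.
    """
    fcs: list[FCMatrix] = []
    records: list[SubjectRecord] = []
    all_ts: list[ROITimeSeries | None] = []
    idx = 0
    for group in ("A", "B"):
        target = _target_matrix(spec, group)
        for k in range(spec.n_subjects_per_group):
            sid = f"{group}{k + 1:04d}"
            rng = _subject_rng(spec.seed, _STREAM_MATRIX, idx)
            fc, ts = _subject_fc(spec, target, rng, sid)
            drng = _subject_rng(spec.seed, _STREAM_DEMOG, idx)
            age = float(drng.uniform(7.0, 58.0))
            gender = "F" if drng.random() < 0.15 else "M"
            fcs.append(fc)
            all_ts.append(ts)
            records.append(SubjectRecord(sid, group, age, gender))
            idx += 1
    if with_timeseries:
        return fcs, records, all_ts
    return fcs, records


def generate_clinical_scores(
    records: list[SubjectRecord], nodal_values, spec: CohortSpec
) -> list[SubjectRecord]:
    """Attach clinical scores to group A subjects.

    score = score_slope * nodal_value + N(0, score_noise_sd); group B
    subjects keep a missing score (mirrors score availability in only
    one group).
    """
    a_records = [r for r in records if r.group == "A"]
    nodal_values = np.asarray(nodal_values, dtype=float)
    if len(nodal_values) != len(a_records):
        raise InputError(
            f"nodal_values length {len(nodal_values)} != "
            f"number of group A subjects {len(a_records)}"
        )
    out: list[SubjectRecord] = []
    ai = 0
    for i, rec in enumerate(records):
        if rec.group == "A":
            rng = _subject_rng(spec.seed, _STREAM_SCORE, ai)
            noise = rng.normal(0.0, spec.score_noise_sd) if spec.score_noise_sd > 0 else 0.0
            score = spec.score_slope * float(nodal_values[ai]) + noise
            out.append(replace(rec, clinical_score=score))
            ai += 1
        else:
            out.append(replace(rec))
    return out


def block_atlas(spec: CohortSpec) -> Atlas:
    """Atlas whose RSN labels are the planted blocks (cycling the seven
    canonical labels when there are at most seven blocks)."""
    lab = spec.block_of()
    if spec.n_blocks <= len(RSN_LABELS):
        names = [RSN_LABELS[k] for k in lab]
    else:
        names = [f"RSN{k + 1}" for k in lab]
    rng = np.random.default_rng([spec.seed, 99])
    centroids = rng.uniform(-70, 70, size=(spec.n_rois, 3)).round(1)
    return Atlas(
        roi_ids=list(range(1, spec.n_rois + 1)),
        names=[f"ROI_{i + 1}" for i in range(spec.n_rois)],
        rsns=names,
        centroids=centroids,
    )


def generate_term_table(
    atlas: Atlas,
    enriched_rsn: str,
    enriched_terms: list[str],
    background_terms: list[str],
    p_hit: float,
    seed: int,
) -> dict[int, list[str]]:
    """ROI -> term list with planted enrichment in one RSN.

    Every ROI carries all background terms; ROIs of ``enriched_rsn``
    additionally carry each enriched term independently with
    probability ``p_hit``.
    """
    if not (0.0 <= p_hit <= 1.0):
        raise InputError(f"p_hit must be in [0, 1], got {p_hit}")
    enriched_rois = set(atlas.rois_in_rsn(enriched_rsn))  # validates label
    rng = np.random.default_rng([seed, _STREAM_TERMS])
    table: dict[int, list[str]] = {}
    for roi in atlas.roi_ids:
        terms = list(background_terms)
        if roi in enriched_rois:
            for t in enriched_terms:
                if rng.random() < p_hit:
                    terms.append(t)
        table[roi] = terms
    return table


def write_subject_table(records: list[SubjectRecord], path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "age": [r.age for r in records],
            "gender": [r.gender for r in records],
            "clinical_score": [
                "" if r.clinical_score is None else r.clinical_score for r in records
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_subject_table(path) -> list[SubjectRecord]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        score = row.get("clinical_score")
        if score is None or (isinstance(score, float) and np.isnan(score)) or score == "":
            score = None
        else:
            score = float(score)
        out.append(
            SubjectRecord(
                str(row["subject_id"]), str(row["group"]), float(row["age"]),
                str(row["gender"]), score,
            )
        )
    return out
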