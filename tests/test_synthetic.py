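import numpy as np
import pytest

from netcurv.errors import ConfigurationError, InputError
from netcurv.synthetic import (
    CohortSpec,
    SubjectRecord,
    block_atlas,
    generate_clinical_scores,
    generate_cohort,
    generate_term_table,
    nearest_correlation,
    read_subject_table,
    write_subject_table,
)


def _spec(**kw):
    base = dict(n_rois=12, n_subjects_per_group=4, n_blocks=2, seed=0)
    base.update(kw)
    return CohortSpec(**base)


class TestCohortSpecValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_rois", 0),
            ("n_subjects_per_group", 0),
            ("n_blocks", 0),
            ("n_blocks", 13),
            ("within_block_mu", 1.0),
            ("between_block_mu", -1.0),
            ("group_effect", -0.1),
            ("noise_sd", -0.5),
            ("n_timepoints", 1),
            ("score_noise_sd", -1.0),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ConfigurationError, match=field):
            _spec(**{field: value})

    def test_blocks_partition_rois(self):
        spec = _spec(n_rois=10, n_blocks=3)
        blocks = spec.blocks
        assert sum(len(b) for b in blocks) == 10
        assert all(len(b) > 0 for b in blocks)


class TestGenerateCohort:
    def test_zero_effect_groups_identical_in_expectation(self):
        spec = _spec(group_effect=0.0, noise_sd=0.0)
        fcs, recs = generate_cohort(spec)
        a = [f for f, r in zip(fcs, recs) if r.group == "A"]
        b = [f for f, r in zip(fcs, recs) if r.group == "B"]
        assert np.array_equal(a[0].matrix, b[0].matrix)

    def test_noiseless_within_block_entries_exact(self):
        spec = _spec(
            n_blocks=2, within_block_mu=0.6, between_block_mu=0.1, noise_sd=0.0
        )
        fcs, recs = generate_cohort(spec)
        fc_b = next(f for f, r in zip(fcs, recs) if r.group == "B")
        blocks = spec.blocks
        for blk in blocks:
            sub = fc_b.matrix[np.ix_(blk, blk)]
            off = sub[~np.eye(len(blk), dtype=bool)]
            assert (off == 0.6).all()
        cross = fc_b.matrix[np.ix_(blocks[0], blocks[1])]
        assert (cross == 0.1).all()

    def test_determinism_bitwise(self):
        spec = _spec(seed=7, noise_sd=0.05, group_effect=0.1)
        fcs1, recs1 = generate_cohort(spec)
        fcs2, recs2 = generate_cohort(spec)
        for f1, f2 in zip(fcs1, fcs2):
            assert np.array_equal(f1.matrix, f2.matrix)
        assert [(r.subject_id, r.age, r.gender) for r in recs1] == [
            (r.subject_id, r.age, r.gender) for r in recs2
        ]

    def test_all_matrices_valid(self):
        spec = _spec(noise_sd=0.2, group_effect=0.3, seed=5)
        fcs, _ = generate_cohort(spec)  # FCMatrix __post_init__ validates
        for fc in fcs:
            assert np.array_equal(fc.matrix, fc.matrix.T)
            assert (np.diag(fc.matrix) == 1.0).all()
            assert (np.abs(fc.matrix) <= 1.0).all()

    def test_group_effect_lowers_within_block_mean(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            spec = _spec(
                n_rois=20,
                n_subjects_per_group=20,
                group_effect=0.2,
                noise_sd=0.05,
                seed=seed,
            )
            fcs, recs = generate_cohort(spec)
            lab = spec.block_of()
            within = lab[:, None] == lab[None, :]
            np.fill_diagonal(within, False)
            means = {"A": [], "B": []}
            for fc, rec in zip(fcs, recs):
                means[rec.group].append(fc.matrix[within].mean())
            if np.mean(means["A"]) < np.mean(means["B"]):
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_timeseries_mode_fc_is_sample_pearson(self):
        spec = _spec(n_timepoints=100, noise_sd=0.02, seed=3)
        fcs, recs, series = generate_cohort(spec, with_timeseries=True)
        for fc, ts in zip(fcs, series):
            assert ts is not None
            expect = np.corrcoef(ts.values)
            assert np.allclose(fc.matrix, expect, atol=1e-12)


class TestNearestCorrelation:
    def test_valid_matrix_unchanged(self):
        mat = np.eye(4)
        mat[0, 1] = mat[1, 0] = 0.5
        assert np.array_equal(nearest_correlation(mat), mat)

    def test_invalid_matrix_projected(self):
        mat = np.array([[1.0, 0.95, -0.95], [0.95, 1.0, 0.95], [-0.95, 0.95, 1.0]])
        fixed = nearest_correlation(mat)
        vals = np.linalg.eigvalsh(fixed)
        assert vals.min() >= -1e-12
        assert np.allclose(np.diag(fixed), 1.0)
        assert np.abs(fixed).max() <= 1.0 + 1e-12


class TestClinicalScores:
    def test_zero_slope_zero_noise(self):
        spec = _spec(score_slope=0.0, score_noise_sd=0.0)
        _, recs = generate_cohort(spec)
        n_a = sum(r.group == "A" for r in recs)
        recs = generate_clinical_scores(recs, np.ones(n_a), spec)
        for r in recs:
            if r.group == "A":
                assert r.clinical_score == 0.0
            else:
                assert r.clinical_score is None

    def test_deterministic_slope(self):
        spec = _spec(score_slope=2.0, score_noise_sd=0.0)
        _, recs = generate_cohort(spec)
        n_a = sum(r.group == "A" for r in recs)
        recs = generate_clinical_scores(recs, np.full(n_a, 1.5), spec)
        scores = [r.clinical_score for r in recs if r.group == "A"]
        assert scores == [3.0] * n_a

    def test_high_snr_correlation(self):
        spec = _spec(
            n_subjects_per_group=200, score_slope=1.0, score_noise_sd=0.1, seed=2
        )
        _, recs = generate_cohort(spec)
        rng = np.random.default_rng(0)
        nodal = rng.standard_normal(200)
        recs = generate_clinical_scores(recs, nodal, spec)
        scores = np.array([r.clinical_score for r in recs if r.group == "A"])
        r = np.corrcoef(scores, nodal)[0, 1]
        assert r > 0.9

    def test_length_mismatch_rejected(self):
        spec = _spec()
        _, recs = generate_cohort(spec)
        with pytest.raises(InputError):
            generate_clinical_scores(recs, [1.0], spec)

    def test_score_only_for_group_a(self):
        with pytest.raises(InputError):
            SubjectRecord("x", "B", 20.0, "M", clinical_score=1.0)


class TestTermTable:
    def test_p_hit_one_all_terms_present(self):
        spec = _spec()
        atlas = block_atlas(spec)
        rsn = atlas.rsns[0]
        table = generate_term_table(atlas, rsn, ["a", "b"], ["bg"], 1.0, seed=0)
        for roi in atlas.rois_in_rsn(rsn):
            assert set(table[roi]) == {"a", "b", "bg"}

    def test_p_hit_zero_no_enrichment(self):
        spec = _spec()
        atlas = block_atlas(spec)
        table = generate_term_table(atlas, atlas.rsns[0], ["a"], ["bg"], 0.0, seed=0)
        assert all("a" not in terms for terms in table.values())

    def test_binomial_support_and_determinism(self):
        spec = _spec(n_rois=20, n_blocks=2)
        atlas = block_atlas(spec)
        rsn = atlas.rsns[0]
        n_enriched_rois = len(atlas.rois_in_rsn(rsn))
        t1 = generate_term_table(atlas, rsn, ["a"], ["bg"], 0.8, seed=4)
        t2 = generate_term_table(atlas, rsn, ["a"], ["bg"], 0.8, seed=4)
        assert t1 == t2
        count = sum("a" in t1[roi] for roi in atlas.rois_in_rsn(rsn))
        assert 0 <= count <= n_enriched_rois

    def test_unknown_rsn_rejected(self):
        spec = _spec()
        atlas = block_atlas(spec)
        with pytest.raises(InputError):
            generate_term_table(atlas, "NoSuchRSN", ["a"], ["bg"], 0.5, seed=0)


class TestSubjectTableIO:
    def test_round_trip(self, tmp_path):
        spec = _spec(score_slope=1.0, score_noise_sd=0.1)
        _, recs = generate_cohort(spec)
        n_a = sum(r.group == "A" for r in recs)
        recs = generate_clinical_scores(recs, np.arange(n_a, dtype=float), spec)
        path = tmp_path / "subjects.tsv"
        write_subject_table(recs, path)
        back = read_subject_table(path)
        assert [r.subject_id for r in back] == [r.subject_id for r in recs]
        for r1, r2 in zip(back, recs):
            assert r1.group == r2.group
            assert r1.age == pytest.approx(r2.age)
            if r2.clinical_score is None:
                assert r1.clinical_score is None
            else:
                assert r1.clinical_score == pytest.approx(r2.clinical_score)
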