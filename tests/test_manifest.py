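"""Cohort manifest I/O, filters, and patient-grouped folds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from survbira.manifest import (
    FoldSplit,
    ManifestError,
    PatientRecord,
    SlideRecord,
    TISSUE_TYPES,
    filter_by_stage,
    filter_by_tissue_type,
    load_manifest,
    make_patient_folds,
)

HEADER = "patient_id,slide_id,image_path,tissue_type,stage,survival_days,cohort\n"


def write_manifest(tmp_path, rows, name="m.csv"):
    path = tmp_path / name
    path.write_text(HEADER + "".join(r + "\n" for r in rows))
    return path


def make_patients(n, stage=1):
    return [
        PatientRecord(patient_id=f"P{i}", survival_days=100 + i, stage=stage)
        for i in range(n)
    ]


class TestLoadManifest:
    def test_groups_slides_into_patients(self, tmp_path):
        path = write_manifest(tmp_path, [
            "P1,S1,a.png,primary_tumor,1,400,c",
            "P1,S2,b.png,primary_tumor,1,400,c",
        ])
        patients, slides = load_manifest(path)
        assert len(patients) == 1 and len(slides) == 2
        assert patients[0].n_slides == 2
        assert patients[0].survival_days == 400

    def test_tsv_delimiter_by_extension(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(HEADER.replace(",", "\t")
                        + "P1\tS1\ta.png\tprimary_tumor\t1\t400\tc\n")
        patients, slides = load_manifest(path)
        assert patients[0].patient_id == "P1"

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("patient_id,slide_id\nP1,S1\n")
        with pytest.raises(ManifestError, match="image_path"):
            load_manifest(path)

    def test_nonpositive_survival_rejected(self, tmp_path):
        path = write_manifest(tmp_path, ["P1,S1,a.png,primary_tumor,1,0,c"])
        with pytest.raises(ManifestError, match="survival_days"):
            load_manifest(path)

    def test_unknown_tissue_type_names_allowed_values(self, tmp_path):
        path = write_manifest(tmp_path, ["P1,S1,a.png,tumor,1,400,c"])
        with pytest.raises(ManifestError, match="primary_tumor"):
            load_manifest(path)

    def test_conflicting_survival_within_patient(self, tmp_path):
        path = write_manifest(tmp_path, [
            "P1,S1,a.png,primary_tumor,1,400,c",
            "P1,S2,b.png,primary_tumor,1,500,c",
        ])
        with pytest.raises(ManifestError, match="survival_days"):
            load_manifest(path)

    def test_slide_count_conservation(self, tmp_path):
        rows = [f"P{i % 3},S{i},x.png,primary_tumor,1,{100 + (i % 3)},c"
                for i in range(7)]
        patients, slides = load_manifest(write_manifest(tmp_path, rows))
        assert sum(p.n_slides for p in patients) == len(slides)


class TestTissueFilter:
    def _slides(self, types):
        return [
            SlideRecord(slide_id=f"S{i}", patient_id="P", image_path="x",
                        tissue_type=t)
            for i, t in enumerate(types)
        ]

    def test_keeps_only_requested_type(self):
        slides = self._slides(["primary_tumor", "lymph_node",
                               "normal_nonneoplastic"])
        kept = filter_by_tissue_type(slides, {"primary_tumor"})
        assert [s.slide_id for s in kept] == ["S0"]

    def test_all_types_is_identity(self):
        slides = self._slides(["primary_tumor", "lymph_node"])
        assert filter_by_tissue_type(slides, set(TISSUE_TYPES)) == slides

    def test_cohort_scale_split(self):
        # A 148-slide cohort split 73 / 27 / 48 by tissue type keeps
        # exactly the 73 primary-tumor slides under the primary-only rule.
        types = (["primary_tumor"] * 73 + ["lymph_node"] * 27
                 + ["normal_nonneoplastic"] * 48)
        slides = self._slides(types)
        assert len(filter_by_tissue_type(slides, {"primary_tumor"})) == 73

    def test_complement_partitions(self):
        slides = self._slides(["primary_tumor", "lymph_node",
                               "normal_nonneoplastic", "primary_tumor"])
        keep = {"primary_tumor"}
        rest = set(TISSUE_TYPES) - keep
        a = filter_by_tissue_type(slides, keep)
        b = filter_by_tissue_type(slides, rest)
        assert sorted(s.slide_id for s in a + b) == sorted(
            s.slide_id for s in slides)

    def test_empty_keep_rejected(self):
        with pytest.raises(ValueError):
            filter_by_tissue_type(self._slides(["primary_tumor"]), set())


class TestStageFilter:
    def test_early_stage_removes_late(self):
        pats = [PatientRecord("P1", 100, 1), PatientRecord("P2", 200, 3)]
        assert filter_by_stage(pats, {1, 2}) == [pats[0]]

    def test_full_range_is_identity(self):
        pats = make_patients(4)
        assert filter_by_stage(pats, {1, 2, 3, 4}) == pats

    def test_empty_patient_list(self):
        assert filter_by_stage([], {1, 2}) == []

    def test_invalid_stage_rejected(self):
        with pytest.raises(ValueError):
            filter_by_stage(make_patients(2), {1, 5})


class TestFolds:
    def test_balanced_even_split(self):
        split = make_patient_folds(make_patients(10), k=5, seed=0)
        sizes = [len(split.fold_patients(f)) for f in range(5)]
        assert sizes == [2] * 5

    def test_deterministic_given_seed(self):
        pats = make_patients(9)
        a = make_patient_folds(pats, k=5, seed=7)
        b = make_patient_folds(pats, k=5, seed=7)
        assert a.assignments == b.assignments

    def test_uneven_sizes_differ_by_at_most_one(self):
        split = make_patient_folds(make_patients(7), k=5, seed=0)
        sizes = sorted(len(split.fold_patients(f)) for f in range(5))
        assert sizes == [1, 1, 1, 2, 2]

    def test_fewer_patients_than_folds_rejected(self):
        with pytest.raises(ValueError):
            make_patient_folds(make_patients(3), k=5, seed=0)

    @settings(deadline=None, max_examples=25)
    @given(n=st.integers(5, 60), k=st.integers(2, 5), seed=st.integers(0, 10))
    def test_every_patient_in_exactly_one_fold(self, n, k, seed):
        pats = make_patients(n)
        split = make_patient_folds(pats, k=k, seed=seed)
        pooled = [p for f in range(k) for p in split.fold_patients(f)]
        assert sorted(pooled) == sorted(p.patient_id for p in pats)
        sizes = [len(split.fold_patients(f)) for f in range(k)]
        assert max(sizes) - min(sizes) <= 1

    def test_csv_round_trip(self, tmp_path):
        split = make_patient_folds(make_patients(6), k=3, seed=1)
        path = tmp_path / "folds.csv"
        split.to_csv(path)
        assert FoldSplit.from_csv(path).assignments == split.assignments
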