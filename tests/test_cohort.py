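"""Tumor-tile sampling caps, patient-exclusive stratified splits and
one-vs-rest assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hesubtype import cohort
from hesubtype.cohort import (SamplingPolicy, StratificationError,
                              assemble_ovr, sample_tumor_tiles,
                              split_patients)


def toy_manifest(tiles_per_wsi: dict[str, int], subtype: dict[str, str],
                 patient: dict[str, str] | None = None) -> pd.DataFrame:
    rows = []
    for wsi, n in tiles_per_wsi.items():
        for i in range(n):
            rows.append({"patient_id": (patient or {}).get(wsi, f"pat_{wsi}"),
                         "wsi_id": wsi, "tile_id": f"{wsi}_T{i:05d}",
                         "x": 0, "y": 0, "tissue_class": "tumor",
                         "subtype": subtype[wsi], "path": ""})
    return pd.DataFrame(rows)


def scores_for(manifest: pd.DataFrame, value: float = 0.9) -> pd.DataFrame:
    return pd.DataFrame({"tile_id": manifest["tile_id"],
                         "score_tumor": value})


class TestSampleTumorTiles:
    def test_cap_applied(self):
        m = toy_manifest({"w1": 1000}, {"w1": "LumA"})
        policy = SamplingPolicy(per_wsi_caps={"LumA": 441}, seed=0)
        subset, no_tumor = sample_tumor_tiles(scores_for(m), m, policy)
        assert len(subset) == 441
        assert no_tumor == []

    def test_small_wsi_keeps_all(self):
        m = toy_manifest({"w1": 200}, {"w1": "LumA"})
        policy = SamplingPolicy(per_wsi_caps={"LumA": 441}, seed=0)
        subset, _ = sample_tumor_tiles(scores_for(m), m, policy)
        assert len(subset) == 200

    def test_cap_all_is_identity(self):
        m = toy_manifest({"w1": 300}, {"w1": "HER2"})
        policy = SamplingPolicy(per_wsi_caps={"HER2": "all"}, seed=0)
        subset, _ = sample_tumor_tiles(scores_for(m), m, policy)
        assert set(subset["tile_id"]) == set(m["tile_id"])

    def test_threshold_excludes_low_scores(self):
        m = toy_manifest({"w1": 10}, {"w1": "LumA"})
        sc = scores_for(m)
        sc.loc[:4, "score_tumor"] = 0.2
        policy = SamplingPolicy(per_wsi_caps={"LumA": "all"},
                                tumor_probability_threshold=0.5)
        subset, _ = sample_tumor_tiles(sc, m, policy)
        assert len(subset) == 5

    def test_no_tumor_wsi_flagged(self):
        m = toy_manifest({"w1": 10, "w2": 10}, {"w1": "BL", "w2": "BL"})
        sc = scores_for(m)
        sc.loc[sc["tile_id"].str.startswith("w2"), "score_tumor"] = 0.1
        subset, no_tumor = sample_tumor_tiles(sc, m, SamplingPolicy())
        assert no_tumor == ["w2"]
        assert set(subset["wsi_id"]) == {"w1"}

    def test_row_order_invariance_and_determinism(self):
        m = toy_manifest({"w1": 500}, {"w1": "LumA"})
        policy = SamplingPolicy(per_wsi_caps={"LumA": 100}, seed=3)
        a, _ = sample_tumor_tiles(scores_for(m), m, policy)
        shuffled = m.sample(frac=1.0, random_state=1).reset_index(drop=True)
        b, _ = sample_tumor_tiles(scores_for(shuffled), shuffled, policy)
        assert list(a["tile_id"]) == list(b["tile_id"])

    def test_missing_scores_rejected(self):
        m = toy_manifest({"w1": 5}, {"w1": "LumA"})
        with pytest.raises(ValueError):
            sample_tumor_tiles(scores_for(m).iloc[:3], m, SamplingPolicy())


def patients_manifest(n_per_class: int, classes=("LumA", "LumB", "HER2", "BL"),
                      wsis_per_patient: int = 1) -> pd.DataFrame:
    rows = []
    for cls in classes:
        for p in range(n_per_class):
            pid = f"{cls}_P{p}"
            for w in range(wsis_per_patient):
                rows.append({"patient_id": pid, "wsi_id": f"{pid}_W{w}",
                             "tile_id": f"{pid}_W{w}_T0", "x": 0, "y": 0,
                             "tissue_class": "tumor", "subtype": cls,
                             "path": ""})
    return pd.DataFrame(rows)


class TestSplitPatients:
    def test_exact_arithmetic_20_per_class(self):
        plan = split_patients(patients_manifest(20), seed=0)
        df = plan.to_frame()
        df["cls"] = df["patient_id"].str.split("_").str[0]
        counts = df.groupby(["cls", "split"]).size().unstack(fill_value=0)
        for cls in ("LumA", "LumB", "HER2", "BL"):
            assert counts.loc[cls, "cnn_train"] + counts.loc[cls, "cnn_val"] == 14
            assert counts.loc[cls, "meta"] == 3
            assert counts.loc[cls, "test"] == 3

    def test_split_exclusive_and_deterministic(self):
        m = patients_manifest(7, wsis_per_patient=2)
        p1 = split_patients(m, seed=4)
        p2 = split_patients(m, seed=4)
        assert p1.assignment == p2.assignment
        # every patient in exactly one split
        assert set(p1.assignment) == set(m["patient_id"])

    def test_too_few_patients(self):
        with pytest.raises(StratificationError):
            split_patients(patients_manifest(2), seed=0)

    def test_no_leakage_across_many_random_cohorts(self):
        for seed in range(20):
            n = int(np.random.default_rng(seed).integers(3, 12))
            m = patients_manifest(n, wsis_per_patient=2)
            plan = split_patients(m, seed=seed)
            cohort.check_no_leakage(plan, m)
            splits = [set(plan.patients(s))
                      for s in ("cnn_train", "cnn_val", "meta", "test")]
            for i in range(4):
                for j in range(i + 1, 4):
                    assert not splits[i] & splits[j]


class TestAssembleOvr:
    def test_balanced_thirds(self):
        m = patients_manifest(1)
        m = pd.concat([m] * 300, ignore_index=True)
        m["tile_id"] = [f"t{i}" for i in range(len(m))]
        out = assemble_ovr(m, "LumA", seed=0)
        assert (out["ovr_label"] == "target").sum() == 300
        neg = out[out["ovr_label"] == "rest"]
        assert len(neg) == 300
        assert (neg.groupby("subtype").size() == 100).all()

    def test_empty_target_rejected(self):
        m = patients_manifest(2)
        with pytest.raises(ValueError):
            assemble_ovr(m[m["subtype"] != "BL"], "BL")

    @settings(max_examples=25, deadline=None)
    @given(counts=st.lists(st.integers(1, 50), min_size=4, max_size=4))
    def test_negatives_never_outnumber_positives(self, counts):
        rows = []
        for cls, n in zip(("A", "B", "C", "D"), counts):
            for i in range(n):
                rows.append({"patient_id": cls, "wsi_id": cls,
                             "tile_id": f"{cls}{i}", "subtype": cls})
        m = pd.DataFrame(rows)
        out = assemble_ovr(m, "A", seed=1)
        n_pos = (out["ovr_label"] == "target").sum()
        n_neg = (out["ovr_label"] == "rest").sum()
        assert n_pos == counts[0]
        assert n_neg <= n_pos

    def test_short_stratum_not_reweighted(self):
        rows = []
        for cls, n in (("A", 90), ("B", 5), ("C", 90), ("D", 90)):
            for i in range(n):
                rows.append({"patient_id": cls, "wsi_id": cls,
                             "tile_id": f"{cls}{i}", "subtype": cls})
        out = assemble_ovr(pd.DataFrame(rows), "A", seed=0)
        neg = out[out["ovr_label"] == "rest"]
        assert neg[neg["subtype"] == "B"].shape[0] == 5
        assert neg[neg["subtype"] == "C"].shape[0] == 30
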