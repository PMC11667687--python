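"""Cohort assembly: tumor-tile sampling, patient-exclusive splits and
one-vs-rest training sets.

The pipeline balances the four subtype classes at the tile level by capping
the number of tumor tiles drawn per WSI, with class-specific caps tuned to
the minority class (defaults LumA: 441, LumB: 1180, BL: 1410, HER2: all).
Slides are then partitioned 70/15/15 into CNN-training, meta-classifier and
test sets with patients as atomic units — a patient's WSIs never straddle
two sets — and the CNN portion is further split 80/20 into train and
validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SamplingPolicy",
    "SplitPlan",
    "sample_tumor_tiles",
    "split_patients",
    "assemble_ovr",
    "check_no_leakage",
    "StratificationError",
    "DEFAULT_CAPS",
]

DEFAULT_CAPS: dict[str, int | str] = {
    "LumA": 441, "LumB": 1180, "BL": 1410, "HER2": "all",
}

SPLIT_NAMES = ("cnn_train", "cnn_val", "meta", "test")


class StratificationError(ValueError):
    """A class has too few patients to populate every split."""


@dataclass(frozen=True)
class SamplingPolicy:
    """Per-WSI tumor-tile caps and the tumor-score admission cutoff."""

    per_wsi_caps: dict = field(default_factory=lambda: dict(DEFAULT_CAPS))
    tumor_probability_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for cls, cap in self.per_wsi_caps.items():
            if cap != "all" and (not isinstance(cap, (int, np.integer)) or cap <= 0):
                raise ValueError(f"cap for {cls!r} must be positive or 'all'")
        if not 0.0 <= self.tumor_probability_threshold <= 1.0:
            raise ValueError("tumor_probability_threshold must lie in [0, 1]")

    def cap_for(self, subtype: str) -> int | None:
        cap = self.per_wsi_caps.get(subtype, "all")
        return None if cap == "all" else int(cap)


@dataclass
class SplitPlan:
    """Patient -> split assignment.

    ``assignment`` maps each patient to one of cnn_train / cnn_val / meta /
    test; cnn_train + cnn_val realize the 70% CNN share split 80/20.
    """

    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    inner_cnn: tuple[float, float] = (0.80, 0.20)
    assignment: dict[str, str] = field(default_factory=dict)

    def patients(self, *splits: str) -> list[str]:
        return sorted(p for p, s in self.assignment.items() if s in splits)

    def subset(self, manifest: pd.DataFrame, *splits: str) -> pd.DataFrame:
        keep = manifest["patient_id"].map(self.assignment).isin(splits)
        return manifest[keep]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.assignment.items()),
                            columns=["patient_id", "split"])


def sample_tumor_tiles(score_table: pd.DataFrame, manifest: pd.DataFrame,
                       policy: SamplingPolicy,
                       ) -> tuple[pd.DataFrame, list[str]]:
    """Select the tumor tiles that feed subtype classification.

    Per WSI: tiles whose tumor score meets the admission threshold are
    pooled; up to the class cap are drawn uniformly without replacement
    (WSIs with fewer admitted tiles keep them all). Returns the selected
    manifest subset plus the list of WSIs with zero admitted tumor tiles —
    those must abstain from slide-level prediction downstream.

    ``score_table`` needs columns ``tile_id`` and ``score_tumor`` covering
    every manifest tile. Selection is invariant to manifest row order.
    """
    scores = score_table.set_index("tile_id")["score_tumor"]
    missing = set(manifest["tile_id"]) - set(scores.index)
    if missing:
        raise ValueError(f"{len(missing)} manifest tiles lack a tumor score")
    m = manifest.sort_values("tile_id").reset_index(drop=True)
    admitted = m[scores.loc[m["tile_id"]].to_numpy()
                 >= policy.tumor_probability_threshold]

    rng = np.random.default_rng(policy.seed)
    picked = []
    no_tumor: list[str] = []
    for wsi_id, group in admitted.groupby("wsi_id", sort=True):
        subtype = _wsi_subtype(manifest, wsi_id)
        cap = policy.cap_for(subtype)
        if cap is None or len(group) <= cap:
            picked.append(group)
        else:
            idx = rng.choice(len(group), size=cap, replace=False)
            picked.append(group.iloc[np.sort(idx)])
    for wsi_id in np.sort(manifest["wsi_id"].unique()):
        if wsi_id not in set(admitted["wsi_id"]):
            no_tumor.append(str(wsi_id))
    subset = (pd.concat(picked, ignore_index=True) if picked
              else admitted.iloc[:0].copy())
    return subset, no_tumor


def _wsi_subtype(manifest: pd.DataFrame, wsi_id: str) -> str:
    vals = manifest.loc[manifest["wsi_id"] == wsi_id, "subtype"]
    vals = vals[vals.astype(str).str.len() > 0]
    return str(vals.iloc[0]) if len(vals) else ""


def _allocate(n: int, fractions: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n items to the given fractions."""
    raw = n * fractions
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def split_patients(manifest: pd.DataFrame,
                   fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                   inner_cnn: tuple[float, float] = (0.80, 0.20),
                   seed: int = 0) -> SplitPlan:
    """Assign patients to cnn_train/cnn_val/meta/test, stratified by
    subtype, with patients atomic (no patient in two splits).

    Each class needs at least 3 patients so every outer split can be
    populated.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("outer fractions must sum to 1")
    if not np.isclose(sum(inner_cnn), 1.0):
        raise ValueError("inner CNN fractions must sum to 1")
    per_patient = (manifest[manifest["subtype"].astype(str).str.len() > 0]
                   .groupby("patient_id")["subtype"].first())
    if per_patient.empty:
        raise ValueError("manifest has no subtype-labeled patients")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    targets = np.array([fractions[0] * inner_cnn[0],
                        fractions[0] * inner_cnn[1],
                        fractions[1], fractions[2]])
    for subtype in sorted(per_patient.unique()):
        patients = np.sort(per_patient[per_patient == subtype].index.to_numpy())
        if len(patients) < 3:
            raise StratificationError(
                f"class {subtype!r} has {len(patients)} patients; "
                "need >= 3 for a 3-way split")
        rng.shuffle(patients)
        # Guarantee each outer split at least one patient, then fill by
        # largest remainder over the four fine-grained splits.
        counts = _allocate(len(patients), targets)
        for outer_idx, fine in ((0, (0, 1)), (1, (2,)), (2, (3,))):
            if sum(counts[i] for i in fine) == 0:
                donor = int(np.argmax(counts))
                counts[donor] -= 1
                counts[fine[0]] += 1
        pos = 0
        for name, cnt in zip(SPLIT_NAMES, counts):
            for p in patients[pos:pos + cnt]:
                assignment[str(p)] = name
            pos += cnt
    plan = SplitPlan(fractions=fractions, inner_cnn=inner_cnn,
                     assignment=assignment)
    check_no_leakage(plan, manifest)
    return plan


def check_no_leakage(plan: SplitPlan, manifest: pd.DataFrame) -> None:
    """Assert that no patient or WSI appears in more than one split."""
    seen: dict[str, str] = {}
    for p, s in plan.assignment.items():
        if p in seen and seen[p] != s:
            raise AssertionError(f"patient {p} assigned to two splits")
        seen[p] = s
    wsi_split = (manifest.assign(split=manifest["patient_id"]
                                 .map(plan.assignment))
                 .groupby("wsi_id")["split"].nunique())
    if (wsi_split > 1).any():
        bad = wsi_split[wsi_split > 1].index.tolist()
        raise AssertionError(f"WSIs straddle splits: {bad}")


def assemble_ovr(manifest: pd.DataFrame, target_class: str,
                 seed: int = 0) -> pd.DataFrame:
    """Build a balanced one-vs-rest tile set for one subtype.

    Positives: every tile of the target class. Negatives: one third of
    N_target drawn uniformly from each of the other three classes (the
    three stratum quotas sum exactly to N_target, so negatives never
    outnumber positives), truncated to availability — short strata are not
    re-weighted. Returns the tile rows plus an ``ovr_label`` column in
    {'target', 'rest'}.
    """
    labeled = manifest[manifest["subtype"].astype(str).str.len() > 0]
    pos = labeled[labeled["subtype"] == target_class]
    if len(pos) == 0:
        raise ValueError(f"no tiles for target class {target_class!r}")
    others = sorted(set(labeled["subtype"].unique()) - {target_class})
    quotas = _allocate(len(pos), np.full(len(others), 1.0 / len(others))) \
        if others else np.array([], dtype=int)
    rng = np.random.default_rng(seed)
    neg_parts = []
    for cls, per_stratum in zip(others, quotas):
        pool = labeled[labeled["subtype"] == cls].sort_values("tile_id")
        k = min(int(per_stratum), len(pool))
        if k < per_stratum:
            import logging
            logging.getLogger(__name__).warning(
                "class %s has only %d tiles (wanted %d) for the rest "
                "stratum of %s", cls, len(pool), per_stratum, target_class)
        idx = rng.choice(len(pool), size=k, replace=False)
        neg_parts.append(pool.iloc[np.sort(idx)])
    neg = pd.concat(neg_parts, ignore_index=True) if neg_parts else pos.iloc[:0]
    out = pd.concat([pos.assign(ovr_label="target"),
                     neg.assign(ovr_label="rest")], ignore_index=True)
    return out
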