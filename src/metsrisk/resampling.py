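"""Repeated train/validation/test splitting with training-set undersampling.

Protocol: one stratified 9:1 train/test split, then thirty repeated 9:1
train/validation re-splits of the training pool.  Class imbalance is
corrected by undersampling the negatives of the *training* portion only
to a 1:1 ratio; validation and test sets keep the natural prevalence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

__all__ = ["Repetition", "SplitPlan", "undersample", "make_split_plan"]


@dataclass(frozen=True)
class Repetition:
    train_ids: tuple
    validation_ids: tuple
    seed: int


@dataclass
class SplitPlan:
    """Test ids plus the repeated (undersampled train, validation) splits."""

    test_ids: tuple
    repetitions: list[Repetition]
    master_seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "master_seed": self.master_seed,
                "test_ids": list(self.test_ids),
                "repetitions": [
                    {
                        "train_ids": list(r.train_ids),
                        "validation_ids": list(r.validation_ids),
                        "seed": r.seed,
                    }
                    for r in self.repetitions
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        d = json.loads(text)
        return cls(
            test_ids=tuple(d["test_ids"]),
            repetitions=[
                Repetition(tuple(r["train_ids"]), tuple(r["validation_ids"]), r["seed"])
                for r in d["repetitions"]
            ],
            master_seed=d["master_seed"],
        )

    def validate(self) -> None:
        test = set(self.test_ids)
        for i, rep in enumerate(self.repetitions):
            tr, va = set(rep.train_ids), set(rep.validation_ids)
            if tr & va:
                raise ValueError(f"repetition {i}: train/validation overlap")
            if (tr | va) & test:
                raise ValueError(f"repetition {i}: leakage into the test set")


def undersample(ids, labels, seed: int):
    """Balance the classes 1:1 by subsampling the majority class.

    All minority-class ids are kept; majority-class ids are drawn without
    replacement down to the minority count.  (In this cohort the minority
    is the MetS-positive class, so all positives are kept.)
    """
    ids = np.asarray(ids)
    labels = np.asarray(labels).astype(bool)
    if len(ids) != len(labels):
        raise ValueError("ids and labels differ in length")
    pos, neg = ids[labels], ids[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("undersampling requires both classes present")
    rng = np.random.default_rng(seed)
    if len(pos) <= len(neg):
        neg = rng.choice(neg, size=len(pos), replace=False)
    else:
        pos = rng.choice(pos, size=len(neg), replace=False)
    out = np.concatenate([pos, neg])
    return out[rng.permutation(len(out))]


def make_split_plan(
    labels: pd.Series,
    test_frac: float = 0.1,
    val_frac: float = 0.1,
    reps: int = 30,
    seed: int = 0,
) -> SplitPlan:
    """Build the full split plan from a label series indexed by record id.

    The test split is stratified by label (variance control); each
    repetition re-splits the remaining pool 9:1 without stratification
    and undersamples its training portion, with a fresh undersample per
    repetition.  Repetition seeds derive from the master seed.
    """
    ids = np.asarray(labels.index)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("cohort must contain both classes")
    pool_ids, test_ids = train_test_split(
        ids, test_size=test_frac, random_state=seed % 2**31, stratify=y
    )
    pool_labels = labels.loc[pool_ids]
    repetitions = []
    for r in range(reps):
        rep_seed = (seed + 1 + r) % 2**31
        train_ids, val_ids = train_test_split(
            np.asarray(pool_ids), test_size=val_frac, random_state=rep_seed
        )
        train_ids = undersample(
            train_ids, pool_labels.loc[train_ids].to_numpy(), rep_seed
        )
        repetitions.append(
            Repetition(tuple(train_ids), tuple(val_ids), seed=rep_seed)
        )
    plan = SplitPlan(tuple(test_ids), repetitions, master_seed=seed)
    plan.validate()
    return plan
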