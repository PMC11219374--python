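"""Duplex train/test partitioning in super-score space, subject-constrained.

The Duplex algorithm (Snee-style alternating max-min assignment) picks
training and test sets that both span the data space: seed the training set
with the two mutually farthest points, the test set with the two farthest
remaining, then alternately give each set the remaining point whose minimum
distance to that set is largest.  Samples are first collapsed to subject
centroids so that all samples from one subject land in the same set.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .datasets import GROUP_QC, MultiBlockDataset
from .errors import DataError


@dataclass
class SplitPlan:
    """Subject-constrained train/test partition of the non-QC samples."""

    train_samples: list[str]
    test_samples: list[str]
    subject_assignment: dict[str, str]  # subject -> "train" | "test"
    test_fraction: float
    n_components: int

    @property
    def train_subjects(self) -> list[str]:
        return sorted(s for s, a in self.subject_assignment.items() if a == "train")

    @property
    def test_subjects(self) -> list[str]:
        return sorted(s for s, a in self.subject_assignment.items() if a == "test")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "train_samples": self.train_samples,
                    "test_samples": self.test_samples,
                    "subject_assignment": self.subject_assignment,
                    "test_fraction": self.test_fraction,
                    "n_components": self.n_components,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        return cls(**json.loads(Path(path).read_text()))


def duplex_split(
    super_scores: pd.DataFrame,
    subjects: pd.Series,
    test_fraction: float = 0.30,
) -> SplitPlan:
    """Split samples into representative train/test sets with Duplex.

    Parameters
    ----------
    super_scores:
        Samples x k score matrix (typically SUM-PCA super scores); only rows
        whose sample id appears in ``subjects`` are partitioned.
    subjects:
        Maps sample_id -> subject_id for every non-QC sample.  Samples
        sharing a subject are collapsed to their centroid and always land in
        the same set.
    test_fraction:
        Fraction of subjects assigned to the test set;
        ``|test subjects| = ceil(test_fraction * n_subjects)``.

    The procedure is fully deterministic; distance ties are broken by
    ascending subject id.
    """
    if not 0 < test_fraction < 1:
        raise DataError(f"test_fraction must be in (0, 1), got {test_fraction}")
    subjects = subjects.dropna()
    sample_ids = [s for s in super_scores.index if s in subjects.index]
    if len(sample_ids) < len(subjects):
        missing = subjects.index.difference(super_scores.index)
        raise DataError(f"super scores lack rows for sample(s) {list(missing)[:5]}")
    scores = super_scores.loc[sample_ids]
    subj_of = subjects.loc[sample_ids]

    centroids = scores.groupby(subj_of).mean()
    centroids = centroids.loc[sorted(centroids.index)]  # ascending subject id for tie-breaks
    subj_ids = list(centroids.index)
    n = len(subj_ids)
    if n < 4:
        raise DataError(f"Duplex needs at least 4 subjects, got {n}")
    quota = math.ceil(test_fraction * n)
    if quota > n - 2:
        raise DataError(
            f"test quota {quota} leaves fewer than the 2 seeding subjects for training (n={n})"
        )

    D = squareform(pdist(centroids.to_numpy()))
    remaining = list(range(n))

    def farthest_pair(pool: list[int]) -> tuple[int, int]:
        best = (-1.0, None)
        for ii, a in enumerate(pool):
            for b in pool[ii + 1 :]:
                d = D[a, b]
                if d > best[0]:  # strict: earliest (lexicographically smallest) pair wins ties
                    best = (d, (a, b))
        return best[1]

    def farthest_from(pool: list[int], members: list[int]) -> int:
        best = (-1.0, None)
        for c in pool:
            d = min(D[c, m] for m in members)
            if d > best[0]:
                best = (d, c)
        return best[1]

    a, b = farthest_pair(remaining)
    train = [a, b]
    for x in (b, a):
        remaining.remove(x)

    test: list[int] = []
    if quota >= 2:
        a, b = farthest_pair(remaining)
        test = [a, b]
        for x in (b, a):
            remaining.remove(x)
    elif quota == 1:
        # a two-point seed would overfill the quota; take the single subject
        # farthest from the training seeds instead
        c = farthest_from(remaining, train)
        test = [c]
        remaining.remove(c)

    turn = "train"
    while remaining:
        if len(test) >= quota:
            train.extend(remaining)
            break
        if len(remaining) <= quota - len(test):
            # just enough subjects left to meet the test quota
            test.extend(remaining)
            break
        members = train if turn == "train" else test
        c = farthest_from(remaining, members)
        members.append(c)
        remaining.remove(c)
        turn = "test" if turn == "train" else "train"

    assignment = {subj_ids[i]: "train" for i in train}
    assignment.update({subj_ids[i]: "test" for i in test})
    train_samples = [s for s in sample_ids if assignment[subj_of[s]] == "train"]
    test_samples = [s for s in sample_ids if assignment[subj_of[s]] == "test"]
    return SplitPlan(
        train_samples=train_samples,
        test_samples=test_samples,
        subject_assignment=assignment,
        test_fraction=test_fraction,
        n_components=super_scores.shape[1],
    )


def random_split(
    subjects: pd.Series, test_fraction: float, seed: int
) -> SplitPlan:
    """Subject-level uniform random split (baseline used in tests only)."""
    rng = np.random.default_rng(seed)
    subjects = subjects.dropna()
    subj_ids = sorted(set(subjects))
    quota = math.ceil(test_fraction * len(subj_ids))
    test_subjects = set(rng.choice(subj_ids, size=quota, replace=False))
    assignment = {s: ("test" if s in test_subjects else "train") for s in subj_ids}
    train_samples = [s for s in subjects.index if assignment[subjects[s]] == "train"]
    test_samples = [s for s in subjects.index if assignment[subjects[s]] == "test"]
    return SplitPlan(
        train_samples=train_samples,
        test_samples=test_samples,
        subject_assignment=assignment,
        test_fraction=test_fraction,
        n_components=0,
    )
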