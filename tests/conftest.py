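"""Shared fixtures: default taxonomy, a trained synthetic system, AUC oracle."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import lymphcascade as lc
from lymphcascade.model_zoo import ModelFamily


@pytest.fixture(scope="session")
def tasks():
    return lc.default_tasks()


@pytest.fixture(scope="session")
def tree():
    return lc.default_hierarchy()


@pytest.fixture(scope="session")
def reference():
    """Packaged published panels / leaf counts / clinical means."""
    return lc.reference_study()


def pair_count_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Exhaustive concordant/discordant pair count: (C + T/2) / (n1 * n0)."""
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    pos = scores[positive]
    neg = scores[~positive]
    concordant = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                concordant += 1
            elif p == q:
                ties += 1
    return (concordant + 0.5 * ties) / (len(pos) * len(neg))


def pair_count_auc_macro(scores: np.ndarray, labels, class_labels) -> float:
    """Macro one-vs-rest mean of the binary pair-counting oracle.

    Two-class tasks follow the standard binary convention: the AUC of the
    positive-class (second) score column alone.
    """
    labels = np.asarray(labels, dtype=object)
    scores = np.asarray(scores)
    if len(class_labels) == 2:
        return pair_count_auc(scores[:, 1], labels == class_labels[1])
    aucs = []
    for j, c in enumerate(class_labels):
        mask = labels == c
        if mask.any() and (~mask).any():
            aucs.append(pair_count_auc(scores[:, j], mask))
    return float(np.mean(aucs))


@pytest.fixture(scope="session")
def auc_oracle():
    return pair_count_auc_macro


@pytest.fixture(scope="session")
def synthetic_split():
    """A train/held-out pair from the study-condition generator."""
    train, _ = lc.generate_cohort(lc.default_config(2500, 101),
                                  cohort_id="train", cohort_tag="train")
    heldout, _ = lc.generate_cohort(
        lc.default_config(1500, 102), cohort_id="heldout",
        cohort_tag="internal_validation", case_prefix="V")
    return train, heldout


@pytest.fixture(scope="session")
def trained_system(synthetic_split, tree):
    train, _ = synthetic_split
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return lc.build_simplified_system(train, tree, ModelFamily.LR, seed=101)
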