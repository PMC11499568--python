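"""Synthetic marker cohorts with controlled prevalences, positivity and missingness.

The generator draws, per case, a subtype leaf from a prevalence map, then each
marker's true status (positive with a leaf-conditional probability, negative
otherwise), then masks statuses to unknown with a per-marker missingness
probability (missing completely at random by default, optionally per leaf).
A per-case "clinically tested" marker count is sampled separately and feeds
the cost comparison.  Markers are conditionally independent given the leaf —
the simplest structure sufficient to exercise every stage of the pipeline;
real IHC data additionally carries correlated stains and
availability-by-indication, which this generator does not emulate.

``default_config`` reproduces the cohort skeleton of the original study's
train set: 84.81% NHL at the root, 77.67% B-cell among NHL, 45.93% DLBCL
among B-cell, with the remaining mass spread over sibling leaves in the
proportions of that study's primary-stage leaf counts, and canonical
immunophenotype positivity profiles (pan-B CD20, pan-T CD3, CD30/CD15 in HL,
CD56/EBERs in NK, CyD1 in MCL, TdT in lymphoblastic leaves, CD10/MUM-1
separating GCB from non-GCB, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .marker_data import CANONICAL_MARKERS, CaseRecord, Cohort, MarkerStatus
from .task_hierarchy import LEAF_LABELS

__all__ = ["GeneratorConfig", "TruthRecord", "generate_cohort",
           "default_config", "DEFAULT_POSITIVITY"]


@dataclass
class GeneratorConfig:
    """Sampling law for one synthetic cohort.

    ``positivity`` maps leaf -> marker -> probability that a *tested* marker
    is positive and must cover every (leaf, marker) pair; ``missingness``
    maps marker -> probability the status is masked to unknown, or leaf ->
    marker -> probability for missingness varying by subtype.
    ``clinical_count_model`` is ``{"kind": "poisson", "mean": ...}`` or
    ``{"kind": "fixed", "value": ...}``.
    """

    n: int
    seed: int
    leaf_prevalence: dict[str, float]
    positivity: dict[str, dict[str, float]]
    missingness: dict = field(default_factory=dict)
    clinical_count_model: dict = field(
        default_factory=lambda: {"kind": "poisson", "mean": 13.3})

    @property
    def leaves(self) -> tuple[str, ...]:
        return tuple(self.leaf_prevalence)

    @property
    def markers(self) -> tuple[str, ...]:
        first = next(iter(self.positivity.values()))
        return tuple(first)

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        prev = np.array(list(self.leaf_prevalence.values()), dtype=float)
        if np.any((prev < 0) | (prev > 1)):
            raise ValueError("prevalences must lie in [0, 1]")
        if abs(prev.sum() - 1.0) > 1e-9:
            raise ValueError(f"prevalences sum to {prev.sum()}, not 1")
        markers = set(self.markers)
        for leaf in self.leaves:
            if leaf not in self.positivity:
                raise ValueError(f"positivity missing for leaf {leaf!r}")
            if set(self.positivity[leaf]) != markers:
                raise ValueError(
                    f"positivity for leaf {leaf!r} must cover all markers")
            for m, p in self.positivity[leaf].items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"positivity({leaf!r}, {m!r}) = {p} "
                                     "outside [0, 1]")
        for key, val in self.missingness.items():
            probs = val.values() if isinstance(val, Mapping) else [val]
            for p in probs:
                if not 0.0 <= float(p) <= 1.0:
                    raise ValueError(f"missingness for {key!r} outside [0, 1]")

    def missing_prob(self, leaf: str, marker: str) -> float:
        val = self.missingness.get(leaf)
        if isinstance(val, Mapping):
            return float(val.get(marker, 0.0))
        return float(self.missingness.get(marker, 0.0))


@dataclass
class TruthRecord:
    """Ground truth of one generated cohort: sampled leaves and pre-missingness statuses."""

    config: GeneratorConfig
    leaves: list[str]
    true_statuses: pd.DataFrame  # bool: marker truly positive, pre-masking


def generate_cohort(config: GeneratorConfig, *, cohort_id: str = "synthetic",
                    cohort_tag: str = "unsplit",
                    case_prefix: str = "S") -> tuple[Cohort, TruthRecord]:
    """Draw one cohort; fully reproducible from ``(config, config.seed)``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    leaves = list(config.leaves)
    markers = list(config.markers)
    prev = np.array([config.leaf_prevalence[l] for l in leaves])
    leaf_idx = rng.choice(len(leaves), size=config.n, p=prev / prev.sum())

    pos_table = np.array([[config.positivity[l][m] for m in markers]
                          for l in leaves])
    miss_table = np.array([[config.missing_prob(l, m) for m in markers]
                           for l in leaves])
    pos_draw = rng.random((config.n, len(markers)))
    miss_draw = rng.random((config.n, len(markers)))
    is_positive = pos_draw < pos_table[leaf_idx]
    is_missing = miss_draw < miss_table[leaf_idx]

    counts = _sample_clinical_counts(config.clinical_count_model, config.n, rng)

    records = []
    for i in range(config.n):
        statuses = {}
        for j, m in enumerate(markers):
            if is_missing[i, j]:
                statuses[m] = MarkerStatus.UNKNOWN
            else:
                statuses[m] = (MarkerStatus.POSITIVE if is_positive[i, j]
                               else MarkerStatus.NEGATIVE)
        records.append(CaseRecord(
            case_id=f"{case_prefix}{i:06d}",
            markers=statuses,
            cohort_tag=cohort_tag,
            subtype_label=leaves[leaf_idx[i]],
            clinical_tested_count=int(counts[i]),
        ))
    truth = TruthRecord(
        config=config,
        leaves=[leaves[i] for i in leaf_idx],
        true_statuses=pd.DataFrame(is_positive, columns=markers),
    )
    return Cohort(cohort_id, records), truth


def _sample_clinical_counts(model: Mapping, n: int,
                            rng: np.random.Generator) -> np.ndarray:
    kind = model.get("kind", "poisson")
    if kind == "poisson":
        return rng.poisson(float(model["mean"]), size=n)
    if kind == "fixed":
        return np.full(n, int(model["value"]))
    raise ValueError(f"unknown clinical_count_model kind {kind!r}")


# ---------------------------------------------------------------------------
# default configuration
# ---------------------------------------------------------------------------

# Conditional prevalence skeleton: the three printed fractions, with the
# remaining mass spread over sibling leaves by the primary-stage leaf counts.
_P_NHL = 0.8481
_P_B_GIVEN_NHL = 0.7767
_P_T_GIVEN_NHL = 0.1330
_P_NK_GIVEN_NHL = 0.0903
_P_DLBCL_GIVEN_B = 0.4593
_B_SIBLING_COUNTS = {"FL": 449, "MZL": 451, "MCL": 126, "BL": 151, "SLL": 86,
                     "PMLBCL": 52, "B-LBL/ALL": 38, "Others": 35}
_COO_COUNTS = {"non-GCB": 519, "GCB": 327}
_T_COUNTS = {"ALCL": 132, "AITL": 102, "TLBL": 137, "PTCL-U": 77}


def _leaf_prevalences() -> dict[str, float]:
    prev: dict[str, float] = {"HL": 1.0 - _P_NHL, "NK-NHL": _P_NHL * _P_NK_GIVEN_NHL}
    p_b = _P_NHL * _P_B_GIVEN_NHL
    p_t = _P_NHL * _P_T_GIVEN_NHL
    b_rest = p_b * (1.0 - _P_DLBCL_GIVEN_B)
    sib_total = sum(_B_SIBLING_COUNTS.values())
    for leaf, c in _B_SIBLING_COUNTS.items():
        prev[leaf] = b_rest * c / sib_total
    p_dlbcl = p_b * _P_DLBCL_GIVEN_B
    coo_total = sum(_COO_COUNTS.values())
    for leaf, c in _COO_COUNTS.items():
        prev[leaf] = p_dlbcl * c / coo_total
    t_total = sum(_T_COUNTS.values())
    for leaf, c in _T_COUNTS.items():
        prev[leaf] = p_t * c / t_total
    # exact unit mass (guards against float drift)
    total = sum(prev.values())
    return {leaf: p / total for leaf, p in prev.items()}


def _profile(base: float = 0.1, **overrides: float) -> dict[str, float]:
    prof = {m: base for m in CANONICAL_MARKERS}
    for name, p in overrides.items():
        # keyword-safe spellings map back onto canonical marker names
        canon = {"MUM1": "MUM-1", "Pax5": "Pax-5", "Bcl6": "Bcl-6",
                 "Bcl2": "Bcl-2", "Cmyc": "C-myc", "CXCL13": "CXCL-13"}
        prof[canon.get(name, name)] = p
    return prof


_B_COMMON = dict(CD20=0.95, CD79=0.9, Pax5=0.9, LCA=0.95, CD3=0.02, CD2=0.05,
                 CD7=0.05, CD43=0.2, Ki67=0.5, Bcl2=0.6)
_T_COMMON = dict(CD3=0.9, CD2=0.9, CD5=0.7, CD7=0.6, CD43=0.8, LCA=0.95,
                 CD20=0.03, Pax5=0.03, CD79=0.05, CD4=0.6, CD8=0.3, Bcl2=0.5,
                 Ki67=0.5)

#: Leaf-conditional positivity of a *tested* marker; plausible canonical
#: immunophenotypes (not calibrated to any deposited dataset).
DEFAULT_POSITIVITY: dict[str, dict[str, float]] = {
    "HL": _profile(CD15=0.8, CD30=0.95, LCA=0.1, CD20=0.2, Pax5=0.7,
                   CD3=0.05, CD5=0.05, CD79=0.15, EBERs=0.4, Ki67=0.6,
                   MUM1=0.85),
    "NK-NHL": _profile(CD56=0.9, CD3=0.6, CD2=0.9, EBERs=0.95, TIA1=0.9,
                       GrB=0.9, Perf=0.85, CD20=0.03, CD5=0.15, CD4=0.1,
                       CD8=0.2, CD7=0.4, CD30=0.3, Ki67=0.7, CD43=0.8,
                       LCA=0.95),
    "GCB": _profile(**{**_B_COMMON, **dict(CD10=0.7, Bcl6=0.85, MUM1=0.2,
                                           CD30=0.15, Ki67=0.8, Cmyc=0.4,
                                           Bcl2=0.5, CD38=0.4)}),
    "non-GCB": _profile(**{**_B_COMMON, **dict(CD10=0.08, Bcl6=0.5, MUM1=0.9,
                                               Ki67=0.8, Cmyc=0.45,
                                               Bcl2=0.65)}),
    "FL": _profile(**{**_B_COMMON, **dict(CD10=0.85, Bcl6=0.9, Bcl2=0.9,
                                          MUM1=0.1, Ki67=0.3, CD23=0.3,
                                          CD21=0.6)}),
    "MZL": _profile(**{**_B_COMMON, **dict(CD10=0.05, CD5=0.05, CD23=0.2,
                                           Bcl2=0.8, CyD1=0.02, CD43=0.3,
                                           Ki67=0.25)}),
    "MCL": _profile(**{**_B_COMMON, **dict(CD5=0.85, CyD1=0.95, CD23=0.15,
                                           Bcl2=0.85, CD10=0.05, Ki67=0.4,
                                           CD43=0.7)}),
    "BL": _profile(**{**_B_COMMON, **dict(CD10=0.9, Bcl6=0.9, Bcl2=0.1,
                                          Ki67=0.97, Cmyc=0.9, MUM1=0.15,
                                          EBERs=0.3)}),
    "SLL": _profile(**{**_B_COMMON, **dict(CD5=0.9, CD23=0.9, CD10=0.03,
                                           CyD1=0.03, Bcl2=0.85, Ki67=0.15,
                                           CD43=0.8)}),
    "PMLBCL": _profile(**{**_B_COMMON, **dict(CD30=0.7, CD23=0.7, CD10=0.1,
                                              MUM1=0.6, Ki67=0.7)}),
    "B-LBL/ALL": _profile(**{**_B_COMMON, **dict(TdT=0.95, CD10=0.8, CD20=0.4,
                                                 LCA=0.7, Ki67=0.8,
                                                 CD38=0.6)}),
    "Others": _profile(**{**_B_COMMON, **dict(CD10=0.2, MUM1=0.3)}),
    "ALCL": _profile(**{**_T_COMMON, **dict(CD30=0.95, ALK=0.7, CD3=0.4,
                                            TIA1=0.7, GrB=0.75, Perf=0.7,
                                            CD5=0.3, CD7=0.25, EBERs=0.05,
                                            Ki67=0.8)}),
    "AITL": _profile(**{**_T_COMMON, **dict(CXCL13=0.85, CD10=0.7, CD4=0.85,
                                            Bcl6=0.7, EBERs=0.4, CD8=0.1,
                                            TIA1=0.2, MUM1=0.4, CD21=0.7)}),
    "TLBL": _profile(**{**_T_COMMON, **dict(TdT=0.95, CD10=0.4, CD4=0.5,
                                            CD8=0.5, CD7=0.9, CD2=0.7,
                                            CD3=0.6, Ki67=0.85, CD30=0.05,
                                            CD56=0.1)}),
    "PTCL-U": _profile(**{**_T_COMMON, **dict(CD4=0.65, CD8=0.25, TIA1=0.4,
                                              GrB=0.35, CD30=0.25, CD5=0.6,
                                              CD7=0.35, EBERs=0.15,
                                              Ki67=0.6)}),
}


def default_config(n: int, seed: int, *, missingness: float = 0.2,
                   clinical_mean: float = 13.3) -> GeneratorConfig:
    """Study-condition defaults: 16 leaves, 32 markers, MCAR missingness 0.2.

    Leaf prevalences honour the printed conditional fractions P(NHL) = 0.8481,
    P(B | NHL) = 0.7767 and P(DLBCL | B) = 0.4593.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = GeneratorConfig(
        n=n,
        seed=int(seed),
        leaf_prevalence=_leaf_prevalences(),
        positivity={leaf: dict(DEFAULT_POSITIVITY[leaf])
                    for leaf in LEAF_LABELS},
        missingness={m: missingness for m in CANONICAL_MARKERS},
        clinical_count_model={"kind": "poisson", "mean": clinical_mean},
    )
    config.validate()
    return config
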