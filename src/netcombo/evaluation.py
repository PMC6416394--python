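"""Benchmark statistics: balanced ROC/AUC, permutation enrichment tests,
bootstrap controls.

Known efficacious combinations are few against a universe of ~n²/2 possible
pairs, and true negatives are unreported; the balanced AUC therefore samples
as many *unknown* pairs as there are positives, repeats the draw, and
averages the AUC over repeats.  Exposure-class enrichment of a labelled pair
set is assessed by a permutation test against equally sized random draws
from the classified universe, with the add-one p-value estimator so p is
never reported as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .cohort import canonical_pair

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AucResult:
    mean_auc: float
    sd_auc: float
    n_repeats: int
    n_pos: int
    n_neg_sampled: int
    seed: int | None


@dataclass(frozen=True)
class PermutationTestResult:
    observed_statistic: float
    null_mean: float
    null_sd: float
    p_value: float
    n_perm: int


def auc_balanced(
    score_by_pair: dict,
    positives,
    universe,
    n_repeats: int = 100,
    seed: int | None = None,
    lower_is_better: bool = True,
) -> AucResult:
    """Mean ROC AUC over repeated balanced negative sampling.

    Each repeat draws ``|positives|`` unknown pairs (universe minus
    positives) uniformly without replacement as negatives and computes the
    AUC of the score ranking (``lower_is_better=True`` for separation
    scores, where smaller s_AB should rank positives first).  Ties are
    handled by the midrank convention.
    """
    positives = {canonical_pair(*p) for p in positives}
    universe = {canonical_pair(*p) for p in universe}
    if not positives:
        raise ValueError("no positive pairs supplied")
    if not positives <= universe:
        raise ValueError("positives must be a subset of the universe")
    unknown = sorted(universe - positives)
    if len(unknown) < len(positives):
        raise ValueError(
            f"universe too small: {len(unknown)} unknown pairs for "
            f"{len(positives)} positives"
        )
    missing = [p for p in list(positives) + unknown if p not in score_by_pair]
    if missing:
        raise KeyError(f"no score for {len(missing)} pairs (e.g. {missing[:3]})")

    pos_sorted = sorted(positives)
    sign = -1.0 if lower_is_better else 1.0
    pos_scores = np.array([sign * score_by_pair[p] for p in pos_sorted])
    unk_scores = np.array([sign * score_by_pair[p] for p in unknown])

    rng = np.random.default_rng(seed)
    aucs = np.empty(n_repeats)
    k = len(pos_sorted)
    for i in range(n_repeats):
        neg_idx = rng.choice(len(unknown), size=k, replace=False)
        y = np.concatenate([np.ones(k), np.zeros(k)])
        s = np.concatenate([pos_scores, unk_scores[neg_idx]])
        aucs[i] = roc_auc_score(y, s)
    return AucResult(
        mean_auc=float(aucs.mean()),
        sd_auc=float(aucs.std()),
        n_repeats=n_repeats,
        n_pos=k,
        n_neg_sampled=k,
        seed=seed,
    )


def permutation_test_class_counts(
    records: pd.DataFrame,
    labeled_pairs,
    target_class: str,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PermutationTestResult:
    """One-sided enrichment of a labelled pair set in one exposure class.

    The statistic is the fraction of labelled pairs classified into
    ``target_class``.  The null draws ``|labeled|`` pairs uniformly without
    replacement from the classified universe, ``n_perm`` times;
    p = (1 + #{null ≥ observed}) / (1 + n_perm), so the smallest reportable
    p is 1/(n_perm + 1).
    """
    keys = [canonical_pair(a, b) for a, b in zip(records["drug_a"], records["drug_b"])]
    class_of = dict(zip(keys, records["exposure_class"]))
    labeled_keys = sorted({canonical_pair(*p) for p in labeled_pairs})
    unknown_labels = [k for k in labeled_keys if k not in class_of]
    if unknown_labels:
        raise ValueError(
            f"{len(unknown_labels)} labelled pairs are not in the classified universe"
        )
    if len(labeled_keys) > len(class_of):
        raise ValueError("labelled set larger than the classified universe")

    is_target = records["exposure_class"].eq(target_class).to_numpy()
    observed = float(np.mean([class_of[k] == target_class for k in labeled_keys]))

    rng = np.random.default_rng(seed)
    n = len(is_target)
    k = len(labeled_keys)
    null = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n, size=k, replace=False)
        null[i] = is_target[idx].mean()
    p = (1.0 + float(np.count_nonzero(null >= observed))) / (1.0 + n_perm)
    return PermutationTestResult(
        observed_statistic=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
        p_value=p,
        n_perm=n_perm,
    )


def bootstrap_adverse_control(
    adverse_pairs,
    n_needed: int,
    n_boot: int = 100,
    seed: int | None = None,
    replace: bool = False,
) -> list:
    """Repeatedly sample control sets of adverse drug–drug interaction pairs.

    Draws ``n_boot`` sets of ``n_needed`` pairs from the adverse pool
    (without replacement within a draw by default), e.g. to match the size
    of a combination benchmark.  Returns a list of lists of canonical pairs.
    """
    pool = sorted({canonical_pair(*p) for p in adverse_pairs})
    if not replace and n_needed > len(pool):
        raise ValueError(
            f"cannot draw {n_needed} pairs without replacement from pool of {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_boot):
        idx = rng.choice(len(pool), size=n_needed, replace=replace)
        draws.append([pool[i] for i in idx])
    return draws
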