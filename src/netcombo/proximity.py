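"""Network distance and proximity measures between protein sets.

Core quantities
---------------
* **Drug–disease closest distance** ``d(X, Y)``: for each disease protein
  ``y`` take the hop distance to its nearest drug target in ``X``, then
  average over the disease set ``Y`` (asymmetric by construction — the
  average runs over disease proteins only).
* **Proximity z-score**: the observed ``d(X, Y)`` standardized against a
  reference distribution of distances between degree-matched random sets,
  ``z = (d − μ)/σ``.  ``z < 0`` means the drug's targets sit inside the
  disease neighborhood.
* **Separation** ``s_AB = ⟨d_AB⟩ − (⟨d_AA⟩ + ⟨d_BB⟩)/2``: the symmetric
  closest distance between two target sets, referenced to each set's
  internal nearest-neighbor distance.  ``s_AB < 0`` — overlapping network
  footprints; ``s_AB ≥ 0`` — topologically separated.
* Four alternative set distances (closest, shortest, kernel, centre) used
  as baselines.

Unreachable node pairs carry no finite distance; every average here skips
them and counts the skips.  A quantity whose every contribution is
unreachable is reported as NaN (an explicit "undefined" sentinel, never
±inf), and downstream classification excludes such records.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .network import DegreeBinning, DistanceCache, sample_degree_matched, shortest_path_lengths_from

logger = logging.getLogger(__name__)

__all__ = [
    "ProximityResult",
    "SeparationResult",
    "closest_distance_drug_disease",
    "proximity_z",
    "separation",
    "distance_closest",
    "distance_shortest",
    "distance_kernel",
    "distance_centre",
    "separation_matrix",
]


@dataclass(frozen=True)
class ProximityResult:
    """Observed closest distance with its degree-matched randomization context."""

    drug: str
    disease: str
    observed_d: float
    mu: float
    sigma: float
    z: float
    n_random: int
    seed: int | None
    skipped_pairs: int


@dataclass(frozen=True)
class SeparationResult:
    drug_a: str
    drug_b: str
    s_ab: float
    mean_d_AA: float
    mean_d_BB: float
    mean_d_AB: float
    n_skipped: int


def _mean_skip_inf(values) -> tuple:
    """Mean of finite values; returns (mean, n_skipped). Empty → (nan, n)."""
    finite = [v for v in values if math.isfinite(v)]
    n_skipped = len(values) - len(finite)
    if not finite:
        return float("nan"), n_skipped
    return float(np.mean(finite)), n_skipped


def closest_distance_drug_disease(g, targets, disease, return_skipped: bool = False):
    """Average over disease proteins of the distance to the nearest drug target.

    Disease proteins that are themselves targets contribute 0.  Disease
    proteins unreachable from every target are skipped (and counted when
    ``return_skipped`` is set).
    """
    targets = set(targets)
    disease = set(disease)
    if not targets or not disease:
        raise ValueError("target and disease sets must be nonempty")
    dist = shortest_path_lengths_from(g, targets)
    values = [float(dist[y]) if y in dist else float("inf") for y in disease]
    d, n_skipped = _mean_skip_inf(values)
    if return_skipped:
        return d, n_skipped
    return d


def proximity_z(
    g,
    binning: DegreeBinning,
    targets,
    disease,
    n_random: int = 1000,
    seed=None,
    randomize: str = "both",
    drug: str = "",
    disease_id: str = "",
) -> ProximityResult:
    """Degree-matched randomization z-score of the drug–disease closest distance.

    Each iteration draws a random set degree-matched to the drug targets
    and (with ``randomize="both"``, the default) another matched to the
    disease proteins, and recomputes the closest distance.  ``z`` is the
    observed distance standardized by the reference mean and s.d.; a
    degenerate reference (σ = 0) yields ``z = NaN`` with a logged
    diagnostic.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`-compatible
    value; fixed seeds give bit-identical results.
    """
    if n_random < 2:
        raise ValueError("n_random must be ≥ 2")
    if randomize not in ("both", "drug"):
        raise ValueError("randomize must be 'both' or 'drug'")
    targets = set(targets)
    disease = set(disease)
    observed, skipped = closest_distance_drug_disease(g, targets, disease, return_skipped=True)

    rng = np.random.default_rng(seed)
    reference = np.empty(n_random)
    for i in range(n_random):
        x_rand = sample_degree_matched(g, binning, targets, rng)
        y_rand = (
            sample_degree_matched(g, binning, disease, rng)
            if randomize == "both"
            else disease
        )
        reference[i] = closest_distance_drug_disease(g, x_rand, y_rand)
    mu = float(np.nanmean(reference))
    sigma = float(np.nanstd(reference))
    if sigma > 0 and math.isfinite(observed):
        z = (observed - mu) / sigma
    else:
        z = float("nan")
        if sigma == 0:
            logger.warning(
                "degenerate reference distribution (σ=0) for drug=%r disease=%r",
                drug, disease_id,
            )
    return ProximityResult(
        drug=drug,
        disease=disease_id,
        observed_d=observed,
        mu=mu,
        sigma=sigma,
        z=z,
        n_random=n_random,
        seed=seed if isinstance(seed, int) else None,
        skipped_pairs=skipped,
    )


def _pairwise(g, a_nodes, b_nodes, cache: DistanceCache | None) -> np.ndarray:
    if cache is None:
        cache = DistanceCache(g)
    return cache.pairwise(a_nodes, b_nodes)


def _closest_terms(matrix: np.ndarray) -> list:
    """Row minima followed by column minima of a pairwise distance matrix."""
    return list(matrix.min(axis=1)) + list(matrix.min(axis=0))


def _within_nearest(g, nodes, cache) -> tuple:
    """⟨d_AA⟩: mean over members of the distance to the nearest *other* member.

    A singleton set has no other member; its internal distance is defined
    as 0 (so two distinct singleton drugs get s_ab = d(a, b)).
    """
    nodes = sorted(nodes)
    if len(nodes) == 1:
        return 0.0, 0
    m = _pairwise(g, nodes, nodes, cache).copy()
    np.fill_diagonal(m, np.inf)
    return _mean_skip_inf(list(m.min(axis=1)))


def separation(g, a_targets, b_targets, cache: DistanceCache | None = None,
               drug_a: str = "", drug_b: str = "") -> SeparationResult:
    """Topological separation of two target modules on the interactome.

    ``s_AB = ⟨d_AB⟩ − (⟨d_AA⟩ + ⟨d_BB⟩)/2`` where ``⟨d_AB⟩`` is the
    symmetric closest distance (targets shared by both drugs contribute 0)
    and ``⟨d_AA⟩``, ``⟨d_BB⟩`` are within-set nearest-neighbor means.
    """
    a_targets, b_targets = set(a_targets), set(b_targets)
    if not a_targets or not b_targets:
        raise ValueError("both target sets must be nonempty")
    if cache is None:
        cache = DistanceCache(g)
    a_sorted, b_sorted = sorted(a_targets), sorted(b_targets)
    m = _pairwise(g, a_sorted, b_sorted, cache)
    d_ab, skip_ab = _mean_skip_inf(_closest_terms(m))
    d_aa, skip_aa = _within_nearest(g, a_targets, cache)
    d_bb, skip_bb = _within_nearest(g, b_targets, cache)
    s = d_ab - (d_aa + d_bb) / 2.0
    return SeparationResult(
        drug_a=drug_a or "",
        drug_b=drug_b or "",
        s_ab=s,
        mean_d_AA=d_aa,
        mean_d_BB=d_bb,
        mean_d_AB=d_ab,
        n_skipped=skip_ab + skip_aa + skip_bb,
    )


def distance_closest(g, a_targets, b_targets, cache=None) -> float:
    """Symmetric closest distance: mean of each node's distance to the nearest
    node of the other set, over |A| + |B| terms."""
    a, b = sorted(set(a_targets)), sorted(set(b_targets))
    if not a or not b:
        raise ValueError("both sets must be nonempty")
    m = _pairwise(g, a, b, cache)
    val, _ = _mean_skip_inf(_closest_terms(m))
    return val


def distance_shortest(g, a_targets, b_targets, cache=None) -> float:
    """All-pairs mean distance over |A| × |B| pairs."""
    a, b = sorted(set(a_targets)), sorted(set(b_targets))
    if not a or not b:
        raise ValueError("both sets must be nonempty")
    m = _pairwise(g, a, b, cache)
    val, _ = _mean_skip_inf(list(m.ravel()))
    return val


def distance_kernel(g, a_targets, b_targets, cache=None) -> float:
    """Exponential-kernel distance down-weighting longer paths.

    ``−1/(|A|+|B|) · [ Σ_a ln Σ_b e^{−(d(a,b)+1)}/|B| + Σ_b ln Σ_a e^{−(d(a,b)+1)}/|A| ]``

    Two singletons at distance d give exactly d + 1.  Unreachable pairs
    contribute a zero kernel weight; a node unreachable from the whole other
    set is skipped.
    """
    a, b = sorted(set(a_targets)), sorted(set(b_targets))
    if not a or not b:
        raise ValueError("both sets must be nonempty")
    m = _pairwise(g, a, b, cache)
    with np.errstate(over="ignore"):
        w = np.exp(-(m + 1.0))  # e^{-inf} = 0 handles unreachable pairs
    terms = []
    row_sums = w.sum(axis=1) / len(b)
    col_sums = w.sum(axis=0) / len(a)
    for s in list(row_sums) + list(col_sums):
        if s > 0:
            terms.append(-math.log(s))
        else:
            terms.append(float("inf"))  # node sees nothing of the other set
    val, _ = _mean_skip_inf(terms)
    return val


def _topological_centres(g, nodes, cache) -> list:
    """All minimizers of the within-set total distance Σ_b d(b, u), u ∈ set."""
    nodes = sorted(nodes)
    m = _pairwise(g, nodes, nodes, cache)
    totals = []
    for j in range(len(nodes)):
        col = m[:, j]
        finite = col[np.isfinite(col)]
        # an unreachable member makes a candidate non-central only if some
        # other candidate reaches more of the set; rank by (−n_reached, total)
        totals.append((-len(finite), float(finite.sum())))
    best = min(totals)
    return [nodes[j] for j, t in enumerate(totals) if t == best]


def distance_centre(g, a_targets, b_targets, cache=None) -> float:
    """Distance between the topological centres of the two sets.

    The centre of a set minimizes the total within-set distance.  When the
    minimizer is not unique, every minimizer is kept and pairwise
    centre-to-centre distances are averaged.
    """
    a, b = set(a_targets), set(b_targets)
    if not a or not b:
        raise ValueError("both sets must be nonempty")
    if cache is None:
        cache = DistanceCache(g)
    ca = _topological_centres(g, a, cache)
    cb = _topological_centres(g, b, cache)
    m = _pairwise(g, ca, cb, cache)
    val, _ = _mean_skip_inf(list(m.ravel()))
    return val


def separation_matrix(g, drug_targets, pairs, cache: DistanceCache | None = None):
    """Separation for every requested drug pair; one table row per pair.

    ``drug_targets`` is a :class:`~netcombo.cohort.DrugTargetMap` (or plain
    dict).  Pairs whose drugs are missing from the map are collected into an
    exclusions table rather than raising.
    Returns ``(results_frame, exclusions_frame)``.
    """
    import pandas as pd

    get = drug_targets.targets.get if hasattr(drug_targets, "targets") else drug_targets.get
    if cache is None:
        cache = DistanceCache(g)
    rows, excluded = [], []
    for a, b in sorted(set(tuple(sorted(p)) for p in pairs)):
        ta, tb = get(a), get(b)
        if ta is None or tb is None:
            excluded.append((a, b, "drug not in target map"))
            continue
        r = separation(g, ta, tb, cache=cache, drug_a=a, drug_b=b)
        rows.append((a, b, r.s_ab, r.mean_d_AA, r.mean_d_BB, r.mean_d_AB, r.n_skipped))
    results = pd.DataFrame(
        rows, columns=["drug_a", "drug_b", "s_ab", "d_aa", "d_bb", "d_ab", "n_skipped"]
    )
    exclusions = pd.DataFrame(excluded, columns=["drug_a", "drug_b", "reason"])
    if len(exclusions):
        logger.info("separation_matrix excluded %d pairs", len(exclusions))
    return results, exclusions
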