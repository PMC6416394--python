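"""Exposure-class classification of drug–drug–disease triples and ranking.

A triple (drug A, drug B, disease) is characterized by three signs:

* ``s_AB`` — are the two target modules separated (≥ 0) or overlapping (< 0)?
* ``z_A``, ``z_B`` — does each drug's module overlap the disease module
  (z < 0) or not (z ≥ 0)?

The 2×2×2 sign space yields six classes (the z signs are unordered):

===========  =========  ================  =======================
``s_AB``     z signs    class             name
===========  =========  ================  =======================
< 0          both < 0   P1                Overlapping Exposure
≥ 0          both < 0   P2                Complementary Exposure
< 0          one < 0    P3                Indirect Exposure
≥ 0          one < 0    P4                Single Exposure
< 0          none < 0   P5                Non-exposure
≥ 0          none < 0   P6                Independent Action
===========  =========  ================  =======================

Complementary Exposure (P2) — both drugs inside the disease module but with
separated target neighborhoods — is the signature of efficacious
combinations; Overlapping Exposure (P1) flags candidate adverse
interactions.  Boundary values (s = 0, z = 0) belong to the "separated"
branches.
"""

from __future__ import annotations

import enum
import logging
import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import canonical_pair
from .network import DistanceCache
from .proximity import proximity_z, separation

logger = logging.getLogger(__name__)


class ExposureClass(str, enum.Enum):
    P1 = "Overlapping Exposure"
    P2 = "Complementary Exposure"
    P3 = "Indirect Exposure"
    P4 = "Single Exposure"
    P5 = "Non-exposure"
    P6 = "Independent Action"

    def __str__(self) -> str:  # "P2" in tables, .value for the long name
        return self.name


@dataclass(frozen=True)
class ExposureRecord:
    drug_a: str
    drug_b: str
    disease: str
    s_ab: float
    z_a: float
    z_b: float
    exposure_class: ExposureClass


def classify_exposure(s_ab: float, z_a: float, z_b: float) -> ExposureClass:
    """Map the three signs to one of the six exposure classes.

    Invariant under swapping (z_a, z_b).  Non-finite inputs are a
    classification error — undefined records must be excluded upstream,
    never silently classified.
    """
    if not (math.isfinite(s_ab) and math.isfinite(z_a) and math.isfinite(z_b)):
        raise ValueError(
            f"cannot classify non-finite inputs s_ab={s_ab}, z_a={z_a}, z_b={z_b}"
        )
    overlapping = s_ab < 0
    n_exposed = int(z_a < 0) + int(z_b < 0)
    if n_exposed == 2:
        return ExposureClass.P1 if overlapping else ExposureClass.P2
    if n_exposed == 1:
        return ExposureClass.P3 if overlapping else ExposureClass.P4
    return ExposureClass.P5 if overlapping else ExposureClass.P6


def _drug_seed(seed: int | None, drug: str) -> np.random.SeedSequence:
    """Per-drug seed derived from (run seed, drug id); order-independent."""
    return np.random.SeedSequence([0 if seed is None else int(seed),
                                   zlib.crc32(drug.encode("utf-8"))])


def drug_disease_z_scores(
    g,
    binning,
    drug_targets,
    disease,
    n_random: int = 1000,
    seed: int | None = None,
    randomize: str = "both",
) -> pd.DataFrame:
    """Proximity z-score of every drug in the map to one disease module.

    Each drug gets its own deterministic sub-seed derived from (seed,
    drug id), so results do not depend on evaluation order.
    """
    targets = drug_targets.targets if hasattr(drug_targets, "targets") else drug_targets
    rows = []
    for drug in sorted(targets):
        res = proximity_z(
            g, binning, targets[drug], disease.members,
            n_random=n_random,
            seed=_drug_seed(seed, drug),
            randomize=randomize,
            drug=drug,
            disease_id=disease.disease_id,
        )
        rows.append((drug, disease.disease_id, res.observed_d, res.mu, res.sigma,
                     res.z, res.n_random, seed, res.skipped_pairs))
    return pd.DataFrame(
        rows,
        columns=["drug", "disease", "d", "mu", "sigma", "z",
                 "n_random", "seed", "n_skipped"],
    )


def classify_all(
    g,
    drug_targets,
    disease,
    pairs,
    binning=None,
    n_random: int = 1000,
    seed: int | None = None,
    min_bin_size: int = 100,
    cache: DistanceCache | None = None,
    z_table: pd.DataFrame | None = None,
):
    """Classify every drug pair against one disease module.

    The per-drug z-score is computed once and shared across all pairs of
    that drug.  Returns ``(records, excluded)`` where ``records`` has one
    row per classifiable pair (columns: drug_a, drug_b, disease, s_ab, z_a,
    z_b, exposure_class) and ``excluded`` lists pairs with undefined s or z.
    """
    from .network import build_degree_bins

    targets = drug_targets.targets if hasattr(drug_targets, "targets") else drug_targets
    members = disease.members & set(g.nodes)
    if not members:
        raise ValueError(f"disease set {disease.disease_id!r} has no in-network genes")
    if members != disease.members:
        logger.info(
            "disease %s: %d of %d genes mapped to network",
            disease.disease_id, len(members), len(disease.members),
        )
        from .cohort import DiseaseGeneSet
        disease = DiseaseGeneSet(disease.disease_id, frozenset(members))

    pairs = sorted(set(canonical_pair(a, b) for a, b in pairs))
    drugs_needed = sorted({d for p in pairs for d in p if d in targets})
    if binning is None:
        binning = build_degree_bins(g, min_bin_size=min(min_bin_size, g.number_of_nodes()))
    if cache is None:
        cache = DistanceCache(g)

    if z_table is None:
        needed_map = {d: targets[d] for d in drugs_needed}
        z_table = drug_disease_z_scores(
            g, binning, needed_map, disease, n_random=n_random, seed=seed,
        )
    z_of = dict(zip(z_table["drug"], z_table["z"]))

    rows, excluded = [], []
    for a, b in pairs:
        if a not in targets or b not in targets:
            excluded.append((a, b, "drug not in target map"))
            continue
        sep = separation(g, targets[a], targets[b], cache=cache, drug_a=a, drug_b=b)
        z_a, z_b = z_of.get(a, float("nan")), z_of.get(b, float("nan"))
        try:
            cls = classify_exposure(sep.s_ab, z_a, z_b)
        except ValueError:
            excluded.append((a, b, "undefined s_ab or z"))
            continue
        rows.append((a, b, disease.disease_id, sep.s_ab, z_a, z_b, cls.name))
    records = pd.DataFrame(
        rows,
        columns=["drug_a", "drug_b", "disease", "s_ab", "z_a", "z_b", "exposure_class"],
    )
    excluded_df = pd.DataFrame(excluded, columns=["drug_a", "drug_b", "reason"])
    if len(excluded_df):
        logger.info("classification excluded %d pairs", len(excluded_df))
    return records, excluded_df


def _filter_sorted(records: pd.DataFrame, class_name: str) -> pd.DataFrame:
    sub = records[records["exposure_class"] == class_name].copy()
    # stable tie-break by the canonical pair id
    sub = sub.sort_values(
        ["s_ab", "drug_a", "drug_b"], kind="mergesort"
    ).reset_index(drop=True)
    sub.insert(0, "rank", range(1, len(sub) + 1))
    return sub


def rank_complementary(
    records: pd.DataFrame,
    restrict_to_drug: str | None = None,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Predicted efficacious combinations: P2 pairs by increasing s_AB.

    Optionally restrict to pairs containing a focal drug and truncate to
    the top k candidates.
    """
    sub = records
    if restrict_to_drug is not None:
        sub = sub[(sub["drug_a"] == restrict_to_drug) | (sub["drug_b"] == restrict_to_drug)]
    out = _filter_sorted(sub, ExposureClass.P2.name)
    if top_k is not None:
        out = out.head(top_k).reset_index(drop=True)
    return out


def adverse_flag_overlapping(records: pd.DataFrame) -> pd.DataFrame:
    """Candidate adverse interactions: P1 (Overlapping Exposure) pairs by
    increasing s_AB."""
    return _filter_sorted(records, ExposureClass.P1.name)
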