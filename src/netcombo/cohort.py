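"""Drug–target maps, disease gene sets and benchmark pair lists.

The drug–target map retains only pharmacologically credible interactions:
rows with a reported binding affinity (Ki, Kd, IC50 or EC50) must pass a
10 µM threshold, and a drug must keep at least two targets to stay in the
map.  Benchmark tables (approved combinations, adverse drug–drug
interactions) are unordered drug-id pairs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

AFFINITY_TYPES = frozenset({"Ki", "Kd", "IC50", "EC50"})

DRUG_TARGET_COLUMNS = ("drug", "target", "affinity_type", "affinity_value_uM")


def canonical_pair(a: str, b: str) -> tuple:
    """Canonical unordered pair: lexicographically (min, max)."""
    return (a, b) if a <= b else (b, a)


@dataclass
class DrugTargetMap:
    """drug id → set of target protein ids, with optional affinity provenance."""

    targets: dict
    provenance: pd.DataFrame | None = None
    excluded: dict = field(default_factory=dict)  # drug -> reason

    @property
    def drugs(self) -> list:
        return sorted(self.targets)

    def __len__(self) -> int:
        return len(self.targets)

    def __getitem__(self, drug: str) -> frozenset:
        return self.targets[drug]

    def __contains__(self, drug: str) -> bool:
        return drug in self.targets

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (drug, target)
            for drug in sorted(self.targets)
            for target in sorted(self.targets[drug])
        ]
        return pd.DataFrame(rows, columns=["drug", "target"])

    def write(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class DiseaseGeneSet:
    """Named disease gene set (e.g. keyed by a MeSH id such as D006973)."""

    disease_id: str
    members: frozenset

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"disease gene set {self.disease_id!r} is empty")


@dataclass(frozen=True)
class PairLabelSet:
    """Gold-standard labelled drug pairs: positives (combinations) and adverse DDIs."""

    positives: frozenset
    adverse: frozenset
    source: str = ""
    allow_overlap: bool = False

    def __post_init__(self):
        if not self.allow_overlap:
            both = self.positives & self.adverse
            if both:
                raise ValueError(
                    f"{len(both)} pairs labelled both positive and adverse "
                    f"(e.g. {sorted(both)[:3]})"
                )


def load_drug_targets(
    table,
    affinity_threshold_uM: float = 10.0,
    min_targets: int = 2,
    require_affinity: bool = False,
    sep: str = "\t",
) -> DrugTargetMap:
    """Load and filter a long-format drug–target table.

    Expected columns: ``drug``, ``target`` and optionally ``affinity_type``
    and ``affinity_value_uM``.  A (drug, target) row survives if any of its
    affinity records is ≤ ``affinity_threshold_uM`` µM, or if it carries no
    numeric affinity at all (curated interactions) unless
    ``require_affinity`` is set.  Drugs with fewer than ``min_targets``
    surviving targets are dropped.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.read_csv(table, sep=sep, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("drug–target table needs at least two columns")
    df = df.rename(columns=dict(zip(df.columns[:4], DRUG_TARGET_COLUMNS)))
    df["drug"] = df["drug"].str.strip()
    df["target"] = df["target"].str.strip()
    df = df[(df["drug"] != "") & (df["target"] != "")]
    n_rows = len(df)

    if "affinity_value_uM" in df.columns:
        value = pd.to_numeric(df["affinity_value_uM"], errors="coerce")
    else:
        value = pd.Series(float("nan"), index=df.index)
    has_affinity = value.notna()
    passes = has_affinity & (value <= affinity_threshold_uM)
    if require_affinity:
        keep = passes
    else:
        keep = passes | ~has_affinity
    dropped_affinity = int((~keep).sum())
    df = df[keep]

    # a (drug, target) pair survives if any record for it survived
    pairs = df[["drug", "target"]].drop_duplicates()
    counts = pairs.groupby("drug")["target"].nunique()
    kept_drugs = set(counts[counts >= min_targets].index)
    excluded = {
        drug: f"only {counts[drug]} target(s) after affinity filter"
        for drug in counts.index
        if drug not in kept_drugs
    }
    pairs = pairs[pairs["drug"].isin(kept_drugs)]

    targets = {
        drug: frozenset(sub["target"])
        for drug, sub in pairs.groupby("drug")
    }
    logger.info(
        "drug–target filter: %d rows in, %d dropped by affinity > %g µM, "
        "%d drugs dropped with < %d targets, %d drugs retained",
        n_rows, dropped_affinity, len(excluded), min_targets, len(targets),
    )
    if not targets:
        logger.warning("no drugs survive filtering; returning empty map")
    provenance = df if "affinity_type" in df.columns else None
    return DrugTargetMap(targets=targets, provenance=provenance, excluded=excluded)


def drug_pair_universe(m: DrugTargetMap) -> set:
    """All unordered drug pairs over the map: exactly n(n−1)/2 pairs."""
    drugs = m.drugs if isinstance(m, DrugTargetMap) else sorted(m)
    if len(drugs) < 2:
        return set()
    return set(itertools.combinations(drugs, 2))


def map_targets_to_network(m: DrugTargetMap, g) -> DrugTargetMap:
    """Restrict every drug's target set to proteins present in the network.

    Drugs left with zero in-network targets are excluded (listed in
    ``excluded``); distances are only defined for in-network proteins.
    """
    nodes = set(g.nodes)
    targets: dict = {}
    excluded = dict(m.excluded)
    n_removed = 0
    for drug, tset in m.targets.items():
        mapped = frozenset(t for t in tset if t in nodes)
        n_removed += len(tset) - len(mapped)
        if mapped:
            targets[drug] = mapped
        else:
            excluded[drug] = "no targets in network"
    n_dropped = len(m.targets) - len(targets)
    if n_removed or n_dropped:
        logger.info(
            "network mapping removed %d off-network targets; "
            "%d drugs excluded with no in-network target", n_removed, n_dropped,
        )
    return DrugTargetMap(targets=targets, provenance=m.provenance, excluded=excluded)


def load_gene_set(path, disease_id: str | None = None) -> DiseaseGeneSet:
    """One-gene-per-line plain list → DiseaseGeneSet (id defaults to filename stem)."""
    import os

    members = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                members.append(line)
    if disease_id is None:
        disease_id = os.path.splitext(os.path.basename(path))[0]
    return DiseaseGeneSet(disease_id=disease_id, members=frozenset(members))


def load_gene_sets_gmt(path) -> dict:
    """GMT-style file (name, description, members…) → {name: DiseaseGeneSet}."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            fields = [f.strip() for f in line.rstrip("\n").split("\t")]
            if len(fields) < 3 or line.startswith("#"):
                continue
            name = fields[0]
            members = frozenset(f for f in fields[2:] if f)
            sets[name] = DiseaseGeneSet(disease_id=name, members=members)
    return sets


def load_pair_list(path, sep: str = "\t", columns=(0, 1)) -> frozenset:
    """Two-column drug-pair table → frozenset of canonical unordered pairs."""
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str, header=None)
    if df.shape[1] < 2:
        raise ValueError("pair list needs two drug-id columns")
    pairs = set()
    n_self = 0
    for a, b in df.iloc[:, list(columns)].itertuples(index=False, name=None):
        if isinstance(a, float) or isinstance(b, float):
            continue
        a, b = a.strip(), b.strip()
        if not a or not b:
            continue
        if a == b:
            n_self += 1
            continue
        pairs.add(canonical_pair(a, b))
    if n_self:
        logger.warning("dropped %d self-pairs from %s", n_self, path)
    return frozenset(pairs)


def restrict_pairs_to_map(pairs, m: DrugTargetMap) -> frozenset:
    """Drop benchmark pairs referencing drugs outside the map (count logged)."""
    kept = frozenset(p for p in pairs if p[0] in m and p[1] in m)
    n_dropped = len(set(pairs)) - len(kept)
    if n_dropped:
        logger.info("dropped %d benchmark pairs with unmapped drugs", n_dropped)
    return kept
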