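"""Deterministic synthetic fixtures: planted-module interactomes with known
ground truth, plus matched similarity inputs.

The generator builds a stochastic-block-model network of several equal
communities, each split into two dense sub-clusters (the two "neighborhoods"
of a module).  One community is the disease module.  Drugs are planted by
placing their target sets inside a chosen sub-cluster (or in an optional
sparse background), with controllable target overlap between drug pairs:

* a drug inside the disease community sits closer to the disease proteins
  than degree-matched random sets (expected z < 0); a drug in any other
  community is farther (expected z > 0);
* two drugs in *different* sub-clusters have separated footprints
  (expected s ≥ 0); a drug copying most of another's targets overlaps it
  (expected s < 0).

Because every community has the same size and density, node degrees are
homogeneous and degree-matched sampling mixes communities freely — which is
what gives the z-score its contrast.  The generator emits a ground-truth
table of these expected signs and classes for pipeline-recovery tests.

Everything is a pure function of the spec (seeded NumPy PCG64 generators
with sub-seeds derived from (seed, component name)), so fixtures are
byte-identical across runs and adding new components never shifts existing
draws.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import DiseaseGeneSet, DrugTargetMap, canonical_pair
from .exposure import classify_exposure

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class DrugPlan:
    """Placement plan for one synthetic drug.

    ``location`` is a module (sub-cluster) index or ``"background"``.  With
    ``overlap_with`` set, a fraction ``overlap_fraction`` of the targets is
    copied from the named drug (which must appear earlier in the plan).
    """

    drug: str
    location: int | str
    n_targets: int = 4
    overlap_with: str | None = None
    overlap_fraction: float = 0.0


#: Default plan: two drugs in the two disease sub-clusters (a
#: Complementary-Exposure pair), a heavily overlapping sibling of the first
#: (Overlapping Exposure), and two drugs in a distant community, one
#: overlapping the other (Non-exposure) — covering planted classes
#: P1, P2, P4 and P5.
DEFAULT_DRUG_PLAN = (
    DrugPlan("drugA", 0, 4),
    DrugPlan("drugB", 1, 4),
    DrugPlan("drugC", 0, 4, overlap_with="drugA", overlap_fraction=0.8),
    DrugPlan("drugD", 6, 4),
    DrugPlan("drugE", 6, 4, overlap_with="drugD", overlap_fraction=0.8),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a planted-module fixture.

    Defaults emulate a small modular interactome: six 30-node communities,
    each made of two 15-node sub-clusters (modules 2k and 2k+1), with
    drug-like target set sizes (a handful of targets per drug).  Module 0/1
    form the disease community.  ``n_nodes`` beyond the module total become
    sparse background nodes (none by default).
    """

    n_nodes: int = 180
    module_sizes: tuple = (15,) * 12
    communities: tuple = tuple((2 * k, 2 * k + 1) for k in range(6))
    disease_modules: tuple = (0, 1)
    p_intra: float = 0.55
    p_community: float = 0.10
    p_inter: float = 0.006
    p_background: float = 0.01
    drugs: tuple = DEFAULT_DRUG_PLAN
    seed: int = 0
    min_lcc_fraction: float = 0.9
    max_regenerations: int = 25

    def __post_init__(self):
        for p in (self.p_intra, self.p_community, self.p_inter, self.p_background):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"edge probability {p} outside [0, 1]")
        if sum(self.module_sizes) > self.n_nodes:
            raise ValueError("module sizes exceed n_nodes")
        grouped = [m for comm in self.communities for m in comm]
        if sorted(grouped) != list(range(len(self.module_sizes))):
            raise ValueError("communities must partition the module indices")
        names = [d.drug for d in self.drugs]
        if len(names) != len(set(names)):
            raise ValueError("duplicate drug names in plan")

    def community_of(self, module) -> int | str:
        if module == "background":
            return "background"
        for i, comm in enumerate(self.communities):
            if module in comm:
                return i
        raise ValueError(f"module {module!r} not in any community")


@dataclass
class FixtureBundle:
    """A generated fixture: graph, disease set, drug map, and ground truth.

    ``truth_drugs`` has one row per drug (expected z sign); ``truth_pairs``
    one row per unambiguous plan pair (expected s sign and exposure class).
    """

    spec: FixtureSpec
    graph: nx.Graph
    disease: DiseaseGeneSet
    drug_targets: DrugTargetMap
    truth_drugs: pd.DataFrame
    truth_pairs: pd.DataFrame
    module_of: dict = field(default_factory=dict)


def _sub_rng(seed: int, component: str) -> np.random.Generator:
    """Deterministic per-component generator derived from (seed, name)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(component.encode())])
    )


def _node_name(i: int) -> str:
    return f"G{i:04d}"


def _block_graph(spec: FixtureSpec, attempt: int) -> tuple:
    """One SBM draw; returns (graph, membership) where membership[i] is the
    module index or −1 for background."""
    rng = _sub_rng(spec.seed, f"graph:{attempt}")
    n = spec.n_nodes
    membership = np.full(n, -1)
    start = 0
    for m, size in enumerate(spec.module_sizes):
        membership[start:start + size] = m
        start += size
    comm = np.array([
        -1 if m < 0 else next(i for i, c in enumerate(spec.communities) if m in c)
        for m in membership
    ])

    prob = np.full((n, n), spec.p_background)
    both_mod = (membership[:, None] >= 0) & (membership[None, :] >= 0)
    same_comm = comm[:, None] == comm[None, :]
    same_mod = membership[:, None] == membership[None, :]
    prob[both_mod] = spec.p_inter
    prob[both_mod & same_comm] = spec.p_community
    prob[both_mod & same_mod] = spec.p_intra

    upper = np.triu(rng.random((n, n)) < prob, k=1)
    g = nx.Graph()
    g.add_nodes_from(_node_name(i) for i in range(n))
    ii, jj = np.nonzero(upper)
    g.add_edges_from((_node_name(i), _node_name(j)) for i, j in zip(ii, jj))
    return g, membership


def _plant_drugs(spec: FixtureSpec, membership: np.ndarray) -> dict:
    """Place each drug's targets per its plan; returns {drug: frozenset}."""
    rng = _sub_rng(spec.seed, "drugs")
    pools = {
        m: [_node_name(i) for i in np.nonzero(membership == m)[0]]
        for m in range(len(spec.module_sizes))
    }
    pools["background"] = [_node_name(i) for i in np.nonzero(membership < 0)[0]]
    placed: dict = {}
    for plan in spec.drugs:
        pool = pools[plan.location]
        shared: list = []
        if plan.overlap_with is not None:
            if plan.overlap_with not in placed:
                raise ValueError(
                    f"{plan.drug} overlaps {plan.overlap_with!r}, which is not placed yet"
                )
            donor = sorted(placed[plan.overlap_with])
            n_shared = min(round(plan.overlap_fraction * plan.n_targets), len(donor))
            shared = list(rng.choice(donor, size=n_shared, replace=False))
        fresh_pool = sorted(set(pool) - set(shared))
        n_fresh = plan.n_targets - len(shared)
        if n_fresh > len(fresh_pool):
            raise ValueError(f"not enough nodes in module {plan.location!r} for {plan.drug}")
        fresh = list(rng.choice(fresh_pool, size=n_fresh, replace=False))
        placed[plan.drug] = frozenset(shared + fresh)
    return placed


def _expected_signs(spec: FixtureSpec) -> tuple:
    """Ground truth: per-drug z sign and per-pair s sign / exposure class.

    A pair is recorded only when its expected separation sign is
    unambiguous: heavy target sharing (overlap fraction ≥ 0.5) → s < 0;
    placement in different modules → s ≥ 0.  Disjoint drugs inside one
    module hover near the s = 0 boundary and are omitted from the truth
    table.
    """
    loc = {d.drug: d.location for d in spec.drugs}
    disease_mods = set(spec.disease_modules)
    z_sign = {
        d.drug: -1 if d.location in disease_mods else 1
        for d in spec.drugs
    }
    overlap = {
        canonical_pair(d.drug, d.overlap_with)
        for d in spec.drugs
        if d.overlap_with and d.overlap_fraction >= 0.5
    }

    rows = []
    for a, b in itertools.combinations(sorted(loc), 2):
        pair = canonical_pair(a, b)
        if pair in overlap:
            s_sign = -1
        elif loc[a] != loc[b]:
            s_sign = 1
        else:
            continue  # disjoint same-module pair: boundary case, no truth
        za, zb = z_sign[pair[0]], z_sign[pair[1]]
        cls = classify_exposure(s_sign * 0.5, za * 0.5, zb * 0.5)
        rows.append((pair[0], pair[1], s_sign, za, zb, cls.name))
    truth_pairs = pd.DataFrame(
        rows,
        columns=["drug_a", "drug_b", "expected_s_sign", "expected_z_a_sign",
                 "expected_z_b_sign", "expected_class"],
    )
    truth_drugs = pd.DataFrame(
        sorted(z_sign.items()), columns=["drug", "expected_z_sign"]
    )
    return truth_drugs, truth_pairs


def generate_planted_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Generate a planted-module fixture with its ground truth.

    Draws are repeated with an incremented sub-seed (logged) until the
    largest connected component covers ``min_lcc_fraction`` of the nodes,
    so distances are defined for essentially every planted pair.
    """
    for attempt in range(spec.max_regenerations):
        g, membership = _block_graph(spec, attempt)
        lcc = max(nx.connected_components(g), key=len)
        if len(lcc) >= spec.min_lcc_fraction * spec.n_nodes:
            if attempt:
                logger.info("fixture connected after %d regeneration(s)", attempt)
            break
    else:
        raise RuntimeError(
            f"could not generate a sufficiently connected graph in "
            f"{spec.max_regenerations} attempts"
        )

    disease_nodes = frozenset(
        _node_name(i)
        for i in np.nonzero(np.isin(membership, list(spec.disease_modules)))[0]
    )
    targets = _plant_drugs(spec, membership)
    truth_drugs, truth_pairs = _expected_signs(spec)
    module_of = {
        _node_name(i): (int(m) if m >= 0 else "background")
        for i, m in enumerate(membership)
    }
    return FixtureBundle(
        spec=spec,
        graph=g,
        disease=DiseaseGeneSet("SYNTHETIC_DISEASE", disease_nodes),
        drug_targets=DrugTargetMap(targets=targets),
        truth_drugs=truth_drugs,
        truth_pairs=truth_pairs,
        module_of=module_of,
    )


# ---------------------------------------------------------------------------
# similarity inputs matched to a fixture

@dataclass
class SimilarityInputs:
    fingerprints: dict
    sequences: dict
    expression: pd.DataFrame
    annotations: dict
    ontology_edges: pd.DataFrame
    atc_codes: dict


def generate_similarity_inputs(
    bundle: FixtureBundle,
    effect: float = 1.0,
    n_tissues: int = 32,
    n_bits: int = 166,
    seq_length: int = 80,
) -> SimilarityInputs:
    """Similarity inputs whose planted signal follows the fixture's overlap plan.

    ``effect`` ∈ [0, 1] scales how strongly overlapping drug pairs (planted
    s < 0) resemble each other: at 1, an overlapping drug inherits its
    partner's fingerprint, a shared ATC prefix and mutation-derived target
    sequences; at 0 every drug is drawn independently.  Expression profiles
    are correlated within modules via a per-module latent tissue profile.
    """
    if not 0.0 <= effect <= 1.0:
        raise ValueError("effect must be in [0, 1]")
    spec = bundle.spec
    drugs = list(spec.drugs)
    rng = _sub_rng(spec.seed, "similarity")

    # --- fingerprints -----------------------------------------------------
    fingerprints: dict = {}
    for plan in drugs:
        if plan.overlap_with and plan.overlap_fraction >= 0.5 and effect > 0:
            base = fingerprints[plan.overlap_with].copy()
            resample = rng.random(n_bits) > effect
            base[resample] = rng.random(int(resample.sum())) < 0.3
            fingerprints[plan.drug] = base
        else:
            fingerprints[plan.drug] = rng.random(n_bits) < 0.3

    # --- target protein sequences ----------------------------------------
    sequences: dict = {}
    aa = np.array(list(AMINO_ACIDS))
    for plan in drugs:
        donor_targets = (
            sorted(bundle.drug_targets[plan.overlap_with])
            if plan.overlap_with and effect > 0 else []
        )
        for t in sorted(bundle.drug_targets[plan.drug]):
            if t in sequences:
                continue
            if donor_targets and rng.random() < effect:
                template = sequences[donor_targets[0]]
                mutate = rng.random(seq_length) < 0.15
                chars = np.array(list(template))
                chars[mutate] = aa[rng.integers(0, len(aa), int(mutate.sum()))]
                sequences[t] = "".join(chars)
            else:
                sequences[t] = "".join(aa[rng.integers(0, len(aa), seq_length)])

    # --- expression (genes × tissues) ------------------------------------
    module_ids = sorted({m for m in bundle.module_of.values()}, key=str)
    latents = {m: rng.normal(size=n_tissues) for m in module_ids}
    genes = sorted(bundle.graph.nodes)
    mat = np.empty((len(genes), n_tissues))
    for i, gene in enumerate(genes):
        m = bundle.module_of[gene]
        w = 0.9 if m != "background" else 0.0
        mat[i] = w * latents[m] + np.sqrt(1 - w**2) * rng.normal(size=n_tissues)
    expression = pd.DataFrame(
        mat, index=genes, columns=[f"tissue{j:02d}" for j in range(n_tissues)]
    )

    # --- toy GO DAG + annotations -----------------------------------------
    # root T:ROOT; one branch term per module; two leaves per branch
    edges = []
    annotations: dict = {}
    for m in module_ids:
        branch = f"T:{m}"
        edges.append((branch, "T:ROOT", "is_a"))
        for leaf_i in range(2):
            leaf = f"T:{m}:{leaf_i}"
            edges.append((leaf, branch, "is_a" if leaf_i == 0 else "part_of"))
    for gene in genes:
        m = bundle.module_of[gene]
        leaf = f"T:{m}:{int(rng.random() < 0.5)}"
        annotations[gene] = {leaf}
    ontology_edges = pd.DataFrame(edges, columns=["child", "parent", "relation"])

    # --- ATC codes ---------------------------------------------------------
    def random_code(r):
        return (
            chr(ord("A") + int(r.integers(0, 14)))
            + f"{int(r.integers(0, 100)):02d}"
            + "".join(chr(ord("A") + int(r.integers(0, 26))) for _ in range(2))
            + f"{int(r.integers(0, 100)):02d}"
        )

    atc_codes: dict = {}
    for plan in drugs:
        if plan.overlap_with and plan.overlap_fraction >= 0.5 and effect > 0:
            donor = sorted(atc_codes[plan.overlap_with])[0]
            # share a prefix depth scaled by effect (0 → none, 1 → full level 5)
            keep = (1, 3, 4, 5, 7)[min(4, int(round(effect * 4)))]
            code = donor[:keep] + random_code(rng)[keep:]
            atc_codes[plan.drug] = {code}
        else:
            atc_codes[plan.drug] = {random_code(rng)}
    return SimilarityInputs(
        fingerprints=fingerprints,
        sequences=sequences,
        expression=expression,
        annotations=annotations,
        ontology_edges=ontology_edges,
        atc_codes=atc_codes,
    )


# ---------------------------------------------------------------------------
# writers — every fixture file uses the exact input format of its reader

def _manifest(paths: dict) -> dict:
    manifest = {}
    for name, path in paths.items():
        with open(path, "rb") as fh:
            manifest[name] = hashlib.sha256(fh.read()).hexdigest()
    return manifest


def write_fixture(bundle: FixtureBundle, outdir) -> dict:
    """Write the fixture in the package's standard input formats.

    Returns {relative filename: sha256 hex digest} (the bundle manifest).
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    edge_path = os.path.join(outdir, "interactome.tsv")
    with open(edge_path, "w") as fh:
        fh.write("# synthetic planted-module interactome\n")
        for u, v in sorted(tuple(sorted(e)) for e in bundle.graph.edges):
            fh.write(f"{u}\t{v}\n")
    paths["interactome.tsv"] = edge_path

    dt_path = os.path.join(outdir, "drug_targets.tsv")
    with open(dt_path, "w") as fh:
        fh.write("drug\ttarget\taffinity_type\taffinity_value_uM\n")
        for drug in sorted(bundle.drug_targets.targets):
            for t in sorted(bundle.drug_targets[drug]):
                fh.write(f"{drug}\t{t}\tKd\t1.0\n")
    paths["drug_targets.tsv"] = dt_path

    gs_path = os.path.join(outdir, "disease_genes.txt")
    with open(gs_path, "w") as fh:
        for gene in sorted(bundle.disease.members):
            fh.write(gene + "\n")
    paths["disease_genes.txt"] = gs_path

    truth_drugs_path = os.path.join(outdir, "truth_drugs.tsv")
    bundle.truth_drugs.to_csv(truth_drugs_path, sep="\t", index=False)
    paths["truth_drugs.tsv"] = truth_drugs_path
    truth_pairs_path = os.path.join(outdir, "truth_pairs.tsv")
    bundle.truth_pairs.to_csv(truth_pairs_path, sep="\t", index=False)
    paths["truth_pairs.tsv"] = truth_pairs_path
    return _manifest(paths)


def write_similarity_inputs(inputs: SimilarityInputs, outdir) -> dict:
    """Write similarity inputs (fingerprint table, FASTA, TSV matrix, GO and
    ATC tables); returns the file manifest."""
    import os

    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    fp_path = os.path.join(outdir, "fingerprints.tsv")
    with open(fp_path, "w") as fh:
        for drug in sorted(inputs.fingerprints):
            bits = "".join("1" if b else "0" for b in inputs.fingerprints[drug])
            fh.write(f"{drug}\t{bits}\n")
    paths["fingerprints.tsv"] = fp_path

    fasta_path = os.path.join(outdir, "target_sequences.fasta")
    records = [
        SeqRecord(Seq(seq), id=target, description="")
        for target, seq in sorted(inputs.sequences.items())
    ]
    SeqIO.write(records, fasta_path, "fasta")
    paths["target_sequences.fasta"] = fasta_path

    expr_path = os.path.join(outdir, "expression.tsv")
    inputs.expression.to_csv(expr_path, sep="\t")
    paths["expression.tsv"] = expr_path

    ann_path = os.path.join(outdir, "go_annotations.tsv")
    with open(ann_path, "w") as fh:
        for gene in sorted(inputs.annotations):
            for term in sorted(inputs.annotations[gene]):
                fh.write(f"{gene}\t{term}\n")
    paths["go_annotations.tsv"] = ann_path

    onto_path = os.path.join(outdir, "go_ontology.tsv")
    inputs.ontology_edges.to_csv(onto_path, sep="\t", index=False, header=False)
    paths["go_ontology.tsv"] = onto_path

    atc_path = os.path.join(outdir, "atc_codes.tsv")
    with open(atc_path, "w") as fh:
        for drug in sorted(inputs.atc_codes):
            for code in sorted(inputs.atc_codes[drug]):
                fh.write(f"{drug}\t{code}\n")
    paths["atc_codes.tsv"] = atc_path
    return _manifest(paths)
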