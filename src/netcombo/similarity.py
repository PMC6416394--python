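"""Pharmacological drug–drug similarity metrics and target-set overlap statistics.

Five profile similarities validate the network separation measure:

* chemical — Tanimoto coefficient of structural fingerprints, T = c/(a+b−c);
* target sequence — mean Smith–Waterman local-alignment similarity over
  cross-drug target pairs (self-comparisons of shared targets excluded);
* co-expression — mean |Pearson correlation| of target-coding genes across
  tissues, optionally restricted to interactome edges;
* functional — mean Gene Ontology semantic similarity (Wang's graph-based
  measure with best-match averaging);
* clinical — ATC-code similarity: level-wise Jaccard of the 5-level code
  hierarchy, averaged over levels (and over code pairs for multi-code drugs).

Target-set overlap statistics (overlap coefficient C, Jaccard J, expected
random overlap, fold change and hypergeometric enrichment/depletion
P-values) provide the network-free baseline.
"""

from __future__ import annotations

import itertools
import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

ATC_CODE_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")
#: character offsets of the 5 ATC levels within a 7-character code
ATC_LEVEL_SLICES = (1, 3, 4, 5, 7)


# ---------------------------------------------------------------------------
# chemical similarity

def tanimoto(fp_a, fp_b) -> float:
    """Tanimoto coefficient T = c/(a + b − c) of two equal-length bit vectors.

    ``a`` and ``b`` are the set-bit counts, ``c`` the common set bits.  Two
    all-zero fingerprints give 0 (no evidence of similarity; the formula
    itself is 0/0).
    """
    fp_a = np.asarray(fp_a, dtype=bool)
    fp_b = np.asarray(fp_b, dtype=bool)
    if fp_a.shape != fp_b.shape:
        raise ValueError(f"fingerprint length mismatch: {fp_a.size} vs {fp_b.size}")
    c = int(np.count_nonzero(fp_a & fp_b))
    denom = int(np.count_nonzero(fp_a)) + int(np.count_nonzero(fp_b)) - c
    return c / denom if denom else 0.0


def parse_fingerprint(bits: str) -> np.ndarray:
    """Parse a '0/1' string (or hex string prefixed 'hex:') into a bool array."""
    bits = bits.strip()
    if bits.startswith("hex:"):
        raw = bits[4:]
        n = len(raw) * 4
        value = int(raw, 16)
        return np.array([(value >> (n - 1 - i)) & 1 for i in range(n)], dtype=bool)
    if not set(bits) <= {"0", "1"}:
        raise ValueError("fingerprint must be a 0/1 string or 'hex:…'")
    return np.frombuffer(bits.encode(), dtype=np.uint8) == ord("1")


def load_fingerprints(path, sep: str = "\t") -> dict:
    """Two-column table (drug, bitstring) → {drug: bool array}; one shared length."""
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str, header=None,
                     names=["drug", "bits"])
    fps = {row.drug.strip(): parse_fingerprint(row.bits) for row in df.itertuples()}
    lengths = {fp.size for fp in fps.values()}
    if len(lengths) > 1:
        raise ValueError(f"mixed fingerprint lengths: {sorted(lengths)}")
    return fps


# ---------------------------------------------------------------------------
# cross-pair enumeration shared by sequence / co-expression / GO metrics

def cross_pairs(targets_a, targets_b):
    """Admissible (a, b) pairs with a ∈ A, b ∈ B and a ≠ b.

    Excluding a = b ensures a target shared by both drugs is never compared
    with itself (which would trivially score 1).
    """
    return [(a, b) for a in sorted(set(targets_a)) for b in sorted(set(targets_b)) if a != b]


# ---------------------------------------------------------------------------
# protein sequence similarity

def _aligner(gap_open: float, gap_extend: float):
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def pairwise_sequence_similarity(
    seq_a: str,
    seq_b: str,
    method: str = "normalized_score",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Smith–Waterman local-alignment similarity of two protein sequences.

    ``method="normalized_score"`` (default) — SW(a,b)/sqrt(SW(a,a)·SW(b,b)),
    the self-score-normalized local alignment score (1 for identical
    sequences, near 0 for unrelated ones).  ``method="identity"`` — fraction
    of identical positions over the optimal local alignment; note this is
    the identity of the best-scoring *segment*, which stays fairly high
    (~0.3) even for unrelated sequences.  BLOSUM62 scoring.
    """
    aligner = _aligner(gap_open, gap_extend)
    if method == "normalized_score":
        s_ab = aligner.score(seq_a, seq_b)
        s_aa = aligner.score(seq_a, seq_a)
        s_bb = aligner.score(seq_b, seq_b)
        if s_aa <= 0 or s_bb <= 0:
            return 0.0
        return max(0.0, float(s_ab) / math.sqrt(s_aa * s_bb))
    if method != "identity":
        raise ValueError(f"unknown sequence similarity method {method!r}")
    alignments = aligner.align(seq_a, seq_b)
    try:
        best = alignments[0]
    except IndexError:
        return 0.0
    counts = best.counts()
    length = best.length
    return counts.identities / length if length else 0.0


def sequence_similarity(
    targets_a,
    targets_b,
    sequences: dict,
    method: str = "normalized_score",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Mean pairwise target-sequence similarity between two drugs.

    Averages over all cross pairs (a, b), a ∈ A, b ∈ B, a ≠ b, whose
    sequences are available.  Returns NaN if no admissible pair exists
    (e.g. both drugs share the one same target).
    """
    pairs = [(a, b) for a, b in cross_pairs(targets_a, targets_b)
             if a in sequences and b in sequences]
    if not pairs:
        return float("nan")
    vals = [
        pairwise_sequence_similarity(sequences[a], sequences[b], method=method,
                                     gap_open=gap_open, gap_extend=gap_extend)
        for a, b in pairs
    ]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# co-expression similarity

def coexpression_similarity(
    targets_a,
    targets_b,
    expression: pd.DataFrame,
    network_restrict=None,
) -> float:
    """Mean |Pearson correlation| across tissues of target-coding gene pairs.

    ``expression`` is a genes × tissues matrix (rows indexed by gene id).
    With ``network_restrict`` (an interactome), only gene pairs that are
    interactome edges are scored — the noise-reduction mapping onto the
    co-expressed interactome.  Constant expression vectors are skipped.
    Returns NaN when no pair can be scored.
    """
    pairs = [(a, b) for a, b in cross_pairs(targets_a, targets_b)
             if a in expression.index and b in expression.index]
    if network_restrict is not None:
        pairs = [(a, b) for a, b in pairs if network_restrict.has_edge(a, b)]
    vals = []
    n_constant = 0
    for a, b in pairs:
        x = expression.loc[a].to_numpy(dtype=float)
        y = expression.loc[b].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            n_constant += 1
            continue
        vals.append(abs(float(np.corrcoef(x, y)[0, 1])))
    if n_constant:
        logger.info("co-expression: skipped %d constant-vector pairs", n_constant)
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def load_expression(path, sep: str = "\t") -> pd.DataFrame:
    """Genes × tissues TSV with a header row and gene ids in the first column."""
    return pd.read_csv(path, sep=sep, comment="#", index_col=0)


# ---------------------------------------------------------------------------
# Gene Ontology semantic similarity (Wang's graph-based measure)

#: semantic contribution decay per edge type
WANG_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class Ontology:
    """Minimal DAG: term → list of (parent, relation) edges."""

    parents: dict = field(default_factory=dict)

    @classmethod
    def from_table(cls, table, sep: str = "\t") -> "Ontology":
        """Edge table with columns (child, parent, relation)."""
        if isinstance(table, pd.DataFrame):
            df = table
        else:
            df = pd.read_csv(table, sep=sep, comment="#", dtype=str, header=None,
                             names=["child", "parent", "relation"])
        parents: dict = {}
        for row in df.itertuples():
            rel = row.relation if isinstance(row.relation, str) else "is_a"
            parents.setdefault(row.child, []).append((row.parent, rel))
            parents.setdefault(row.parent, [])
        onto = cls(parents=parents)
        onto._check_acyclic()
        return onto

    def _check_acyclic(self):
        import networkx as nx

        dag = nx.DiGraph(
            (child, parent)
            for child, edges in self.parents.items()
            for parent, _ in edges
        )
        if dag.number_of_nodes() and not nx.is_directed_acyclic_graph(dag):
            raise ValueError("ontology parent relation contains a cycle")

    def s_values(self, term: str, weights=None) -> dict:
        """Wang semantic contributions of ``term``'s ancestors (incl. itself).

        S(term) = 1; walking up an edge multiplies by the edge weight; each
        ancestor keeps the maximum contribution over all downward paths.
        """
        if term not in self.parents:
            raise KeyError(f"unknown ontology term {term!r}")
        weights = weights or WANG_WEIGHTS
        s = {term: 1.0}
        frontier = [term]
        while frontier:
            nxt = []
            for t in frontier:
                for parent, rel in self.parents.get(t, ()):
                    w = weights.get(rel, min(weights.values()))
                    cand = s[t] * w
                    if cand > s.get(parent, 0.0):
                        s[parent] = cand
                        nxt.append(parent)
            frontier = nxt
        return s


def wang_term_similarity(t1: str, t2: str, ontology: Ontology, weights=None) -> float:
    """Wang similarity of two ontology terms.

    sim = Σ_{t ∈ anc(t1) ∩ anc(t2)} (S₁(t) + S₂(t)) / (SV(t1) + SV(t2));
    terms in disjoint DAG components share no ancestor and score 0.
    """
    s1 = ontology.s_values(t1, weights)
    s2 = ontology.s_values(t2, weights)
    common = s1.keys() & s2.keys()
    if not common:
        return 0.0
    num = sum(s1[t] + s2[t] for t in common)
    return num / (sum(s1.values()) + sum(s2.values()))


def wang_gene_similarity(terms_a, terms_b, ontology: Ontology, weights=None) -> float:
    """Best-match-average combination of term similarities for two genes."""
    terms_a, terms_b = sorted(set(terms_a)), sorted(set(terms_b))
    if not terms_a or not terms_b:
        return float("nan")
    sim = np.array(
        [[wang_term_similarity(t1, t2, ontology, weights) for t2 in terms_b]
         for t1 in terms_a]
    )
    return float((sim.max(axis=1).sum() + sim.max(axis=0).sum())
                 / (len(terms_a) + len(terms_b)))


def go_similarity(
    genes_a,
    genes_b,
    annotations: dict,
    ontology: Ontology,
    branch: str | None = None,
    weights=None,
) -> float:
    """Mean Wang semantic similarity over cross gene pairs a ≠ b.

    ``annotations`` maps gene → set of terms (already restricted to one GO
    branch; pass ``branch`` only for bookkeeping).  Unannotated genes are
    skipped with a count; no scoreable pair → NaN.
    """
    pairs = [(a, b) for a, b in cross_pairs(genes_a, genes_b)
             if annotations.get(a) and annotations.get(b)]
    n_all = len(cross_pairs(genes_a, genes_b))
    if n_all and len(pairs) < n_all:
        logger.info("GO similarity (%s): %d/%d pairs unannotated, skipped",
                    branch or "?", n_all - len(pairs), n_all)
    if not pairs:
        return float("nan")
    vals = [wang_gene_similarity(annotations[a], annotations[b], ontology, weights)
            for a, b in pairs]
    vals = [v for v in vals if not math.isnan(v)]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def load_annotations(path, sep: str = "\t") -> dict:
    """Two-column (gene, term) table → {gene: set of terms}."""
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str, header=None,
                     names=["gene", "term"])
    out: dict = {}
    for row in df.itertuples():
        out.setdefault(row.gene.strip(), set()).add(row.term.strip())
    return out


# ---------------------------------------------------------------------------
# clinical (ATC) similarity

def validate_atc_code(code: str) -> str:
    code = code.strip()
    if not ATC_CODE_RE.match(code):
        raise ValueError(f"malformed ATC code {code!r} (expected letter, 2 digits, "
                         "2 letters, 2 digits)")
    return code


def _single_code_similarity(code_a: str, code_b: str) -> float:
    """Mean over the 5 levels of prefix agreement of two single ATC codes."""
    return sum(code_a[:k] == code_b[:k] for k in ATC_LEVEL_SLICES) / len(ATC_LEVEL_SLICES)


def atc_similarity(codes_a, codes_b) -> float:
    """Clinical similarity from ATC codes.

    For single-code drugs: per level k = 1…5, the Jaccard of level-k prefixes
    (for single codes, 1 if the prefixes agree, else 0), averaged over the
    five levels.  Drugs with multiple ATC codes are scored per code pair and
    the scores averaged.
    """
    codes_a = [validate_atc_code(c) for c in sorted(set(codes_a))]
    codes_b = [validate_atc_code(c) for c in sorted(set(codes_b))]
    if not codes_a or not codes_b:
        raise ValueError("both drugs need at least one ATC code")
    scores = [_single_code_similarity(a, b) for a in codes_a for b in codes_b]
    return float(np.mean(scores))


def load_atc_codes(path, sep: str = "\t") -> dict:
    """Two-column (drug, code) table, one row per code → {drug: set of codes}."""
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str, header=None,
                     names=["drug", "code"])
    out: dict = {}
    for row in df.itertuples():
        out.setdefault(row.drug.strip(), set()).add(validate_atc_code(row.code))
    return out


# ---------------------------------------------------------------------------
# target-set overlap statistics

@dataclass(frozen=True)
class OverlapStats:
    c_obs: int
    c_rand: float
    fold_change: float
    p_enrich: float
    p_deplete: float
    overlap_coefficient: float
    jaccard: float


def overlap_stats(targets_a, targets_b, n_background: int) -> OverlapStats:
    """Network-free overlap of two target sets against N background proteins.

    c_rand = |A|·|B|/N is the overlap expected if targets were placed
    uniformly at random among the N proteins; fold change fc = c_obs/c_rand.
    Enrichment and depletion P-values are exact hypergeometric tail
    probabilities P[X ≥ c_obs] and P[X ≤ c_obs].
    """
    a, b = set(targets_a), set(targets_b)
    if not a or not b:
        raise ValueError("both target sets must be nonempty")
    if n_background < len(a | b):
        raise ValueError(
            f"background size {n_background} smaller than |A ∪ B| = {len(a | b)}"
        )
    c_obs = len(a & b)
    c_rand = len(a) * len(b) / n_background
    rv = hypergeom(n_background, len(a), len(b))
    return OverlapStats(
        c_obs=c_obs,
        c_rand=c_rand,
        fold_change=c_obs / c_rand,
        p_enrich=float(rv.sf(c_obs - 1)),
        p_deplete=float(rv.cdf(c_obs)),
        overlap_coefficient=c_obs / min(len(a), len(b)),
        jaccard=c_obs / len(a | b),
    )


# ---------------------------------------------------------------------------
# combined per-pair profile

def similarity_profile(
    drug_a: str,
    drug_b: str,
    drug_targets=None,
    fingerprints: dict | None = None,
    sequences: dict | None = None,
    expression: pd.DataFrame | None = None,
    annotations: dict | None = None,
    ontology: Ontology | None = None,
    atc_codes: dict | None = None,
    interactome=None,
    n_background: int | None = None,
) -> dict:
    """Every similarity metric whose inputs were supplied, for one drug pair.

    Missing inputs yield ``None`` markers; metrics that are defined but not
    computable on this pair (e.g. no admissible sequence pair) yield NaN.
    """
    out: dict = {"drug_a": drug_a, "drug_b": drug_b}
    ta = tb = None
    if drug_targets is not None and drug_a in drug_targets and drug_b in drug_targets:
        ta, tb = drug_targets[drug_a], drug_targets[drug_b]

    out["tanimoto"] = (
        tanimoto(fingerprints[drug_a], fingerprints[drug_b])
        if fingerprints and drug_a in fingerprints and drug_b in fingerprints
        else None
    )
    out["sequence"] = (
        sequence_similarity(ta, tb, sequences)
        if sequences and ta is not None else None
    )
    out["coexpression"] = (
        coexpression_similarity(ta, tb, expression, network_restrict=interactome)
        if expression is not None and ta is not None else None
    )
    out["go"] = (
        go_similarity(ta, tb, annotations, ontology)
        if annotations and ontology is not None and ta is not None else None
    )
    out["atc"] = (
        atc_similarity(atc_codes[drug_a], atc_codes[drug_b])
        if atc_codes and drug_a in atc_codes and drug_b in atc_codes
        else None
    )
    if ta is not None and n_background:
        stats = overlap_stats(ta, tb, n_background)
        out["jaccard"] = stats.jaccard
        out["overlap_coefficient"] = stats.overlap_coefficient
    else:
        out["jaccard"] = out["overlap_coefficient"] = None
    return out
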