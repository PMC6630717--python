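"""Self-contained synthetic inputs with the statistical structure the method assumes.

Real studies of domain-composition profiling start from hundreds of RefSeq
genomes and a profile-HMM domain scanner. This module provides a desk-scale
stand-in with known ground truth:

* a random phylogeny (:func:`simulate_tree`);
* domain repertoires evolving on it by gain / loss / duplication
  (:func:`evolve_repertoires`), so that closely related leaves share more of
  their repertoire — the premise the profiling method rests on;
* genomes that embed each domain copy as a short amino-acid motif inside a
  random protein, reverse-translated into ORFs at a target coding density
  (:func:`emit_genome`);
* a deterministic exact-match motif scanner (:func:`toy_scan`) playing the
  role of the domain-database search, so matrix-level expectations are exact;
* marker genes evolving on the same tree under a symmetric substitution
  model (:func:`evolve_marker`);
* multi-sample communities whose mixture weights depend on covariates such
  as filter pore size and season (:func:`simulate_environment`).

All rates are stand-ins chosen for a clear signal at small problem sizes,
not estimates from any real dataset. A single study seed fans out into
per-stage child seeds (:func:`child_seed`) so stages are independently
reproducible.
"""

from __future__ import annotations

import datetime as _dt
import math
import zlib
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .containers import DistanceMatrix
from .formats_io import DomainHit, SampleMetadata

AA20 = "ACDEFGHIKLMNPQRSTVWY"
DNA4 = "ACGT"

#: codons per amino acid for uniform reverse translation (standard code)
_CODONS_BY_AA: dict[str, list[str]] = {}
from Bio.Data.CodonTable import standard_dna_table as _std  # noqa: E402

for _codon, _aa in _std.forward_table.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_BY_AA:
    _CODONS_BY_AA[_aa].sort()
_STOPS = sorted(_std.stop_codons)


def child_seed(seed: int, tag: str) -> int:
    """Derive a per-stage seed (< 2^31) from the study seed and a stage tag."""
    return (int(seed) * 1_000_003 + zlib.crc32(tag.encode())) % (2**31)


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

#: mean of the exponential branch-length distribution
BRANCH_LENGTH_MEAN = 0.1


def simulate_tree(n_leaves: int, seed: int = 0) -> dendropy.Tree:
    """Random rooted binary tree by uniform sequential joins.

    Leaf labels are ``sp001..spNNN``; every edge gets an i.i.d.
    exponential(mean 0.1) length. Deterministic per seed.
    """
    if n_leaves < 2:
        raise ValueError(f"need at least 2 leaves, got {n_leaves}")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"sp{i + 1:03d}" for i in range(n_leaves)])
    nodes = []
    for taxon in taxa:
        node = dendropy.Node(taxon=taxon)
        node.edge.length = float(rng.exponential(BRANCH_LENGTH_MEAN))
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.exponential(BRANCH_LENGTH_MEAN))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.edge.length = None
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = True
    return tree


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length (patristic) distance matrix of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = [t.label for t in tree.taxon_namespace]
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(tree.taxon_namespace[i], tree.taxon_namespace[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(pd.DataFrame(values, index=labels, columns=labels), model="patristic")


# ---------------------------------------------------------------------------
# Domain vocabulary and repertoires
# ---------------------------------------------------------------------------

class VocabularyError(ValueError):
    """Motif set violates the no-collision constraint."""


def make_vocabulary(
    n_domains: int = 600,
    seed: int = 0,
    min_len: int = 8,
    max_len: int = 12,
) -> dict[str, str]:
    """Random motif vocabulary: domain id -> fixed amino-acid motif (8-12 aa).

    Motifs are distinct and none is a substring of another, so exact-match
    scanning is unambiguous. Motif length is kept short enough that a 33-aa
    translated 100 bp read frame can contain a whole motif.
    """
    if not 1 <= min_len <= max_len:
        raise ValueError("need 1 <= min_len <= max_len")
    rng = np.random.default_rng(seed)
    motifs: list[str] = []
    blob = ""
    while len(motifs) < n_domains:
        length = int(rng.integers(min_len, max_len + 1))
        motif = "".join(rng.choice(list(AA20), size=length))
        if motif in blob or any(motif in m or m in motif for m in motifs):
            continue  # substring collision: resample
        motifs.append(motif)
        blob += "|" + motif
    return {f"DOM{i + 1:04d}": m for i, m in enumerate(motifs)}


def check_vocabulary(vocabulary: Mapping[str, str]) -> None:
    """Raise :class:`VocabularyError` on duplicate or nested motifs."""
    motifs = list(vocabulary.values())
    if len(set(motifs)) != len(motifs):
        raise VocabularyError("duplicate motifs in vocabulary")
    for i, a in enumerate(motifs):
        for j, b in enumerate(motifs):
            if i != j and a in b:
                raise VocabularyError(f"motif {a!r} is a substring of {b!r}")


def evolve_repertoires(
    tree: dendropy.Tree,
    vocabulary: Mapping[str, str],
    gain_rate: float = 450.0,
    loss_rate: float = 3.0,
    copy_rate: float = 2.0,
    seed: int = 0,
    root_size: int | None = None,
) -> dict[str, Counter]:
    """Evolve per-leaf domain repertoires (multisets) along a tree.

    The root holds ``root_size`` distinct domain types at copy number 1
    (default: half the vocabulary). Along each branch of length ``t``, every
    present type is lost with probability ``1 - exp(-loss_rate * t)``;
    surviving types duplicate as a birth process, each copy independently
    adding one extra copy with probability ``1 - exp(-copy_rate * t)`` (so a
    single-copy type goes to 2 copies with exactly that probability, and
    multi-copy families grow multiplicatively, giving the overdispersed,
    heavy-tailed copy numbers real domain profiles show);
    ``Poisson(gain_rate * t)`` new types (drawn from the unused vocabulary)
    are gained at copy 1. Lineages below a node evolve independently.
    """
    if not vocabulary:
        raise ValueError("vocabulary must be non-empty")
    if min(gain_rate, loss_rate, copy_rate) < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    all_ids = sorted(vocabulary)
    if root_size is None:
        root_size = max(1, len(all_ids) // 2)
    if root_size > len(all_ids):
        raise ValueError("root_size exceeds vocabulary size")
    root_ids = rng.choice(all_ids, size=root_size, replace=False)
    root_rep = Counter({d: 1 for d in root_ids})

    repertoires: dict[str, Counter] = {}

    def descend(node: dendropy.Node, rep: Counter) -> None:
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            p_loss = 1 - math.exp(-loss_rate * t)
            p_copy = 1 - math.exp(-copy_rate * t)
            new_rep: Counter = Counter()
            for dom, copies in sorted(rep.items()):
                if rng.random() < p_loss:
                    continue
                new_rep[dom] = copies + int(rng.binomial(copies, p_copy))
            n_gain = rng.poisson(gain_rate * t)
            absent = [d for d in all_ids if d not in new_rep]
            if n_gain and absent:
                gained = rng.choice(absent, size=min(n_gain, len(absent)), replace=False)
                for d in gained:
                    new_rep[d] = 1
            if child.is_leaf():
                repertoires[child.taxon.label] = new_rep
            else:
                descend(child, new_rep)

    root = tree.seed_node
    if root.is_leaf():  # pragma: no cover - trees here always have >= 2 leaves
        repertoires[root.taxon.label] = root_rep
    descend(root, root_rep)
    return repertoires


def repertoire_matrix(repertoires: Mapping[str, Counter]) -> "DomainCountMatrix":
    """True domain x species count matrix straight from the repertoires."""
    from .containers import DomainCountMatrix

    df = (
        pd.DataFrame({sp: dict(rep) for sp, rep in sorted(repertoires.items())})
        .fillna(0)
        .astype(int)
        .sort_index()
    )
    df.index.name = "domain_id"
    return DomainCountMatrix(df, transform="raw")


def inject_high_copy_domains(
    repertoires: Mapping[str, Counter],
    vocabulary: Mapping[str, str],
    n_domains: int = 8,
    copies: tuple[int, int] = (50, 200),
    lineage_prob: float = 0.5,
    seed: int = 0,
) -> dict[str, Counter]:
    """Add a few very high-copy domains to random lineages.

    Models domain families a genome carries "in large amounts" independently
    of phylogeny (transposases, ABC transporters and the like): each chosen
    domain is assigned to a random subset of lineages at a uniform copy
    number in ``copies``. These swamp raw-count correlations while leaving
    presence/absence structure intact, which is exactly the situation the
    binary and log transforms are meant to fix.
    """
    rng = np.random.default_rng(seed)
    chosen = rng.choice(sorted(vocabulary), size=n_domains, replace=False)
    out = {sp: Counter(rep) for sp, rep in repertoires.items()}
    for dom in chosen:
        for sp in sorted(out):
            if rng.random() < lineage_prob:
                out[sp][dom] = int(rng.integers(copies[0], copies[1] + 1))
    return out


# ---------------------------------------------------------------------------
# Genome emission
# ---------------------------------------------------------------------------

def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [_CODONS_BY_AA[aa][rng.integers(len(_CODONS_BY_AA[aa]))] for aa in protein]
    return "".join(codons)


def emit_genome(
    repertoire: Mapping[str, int],
    vocabulary: Mapping[str, str],
    coding_fraction: float = 0.8,
    seed: int = 0,
    protein_len_range: tuple[int, int] = (60, 300),
    species_id: str = "genome",
) -> tuple[str, list[tuple[str, str]]]:
    """Turn a domain repertoire into a genome plus its exact proteome.

    Every domain copy becomes one random protein (60-300 aa, starting with M)
    with the domain's motif embedded at a random position. Proteins are
    reverse-translated with uniform codon choice into ATG..stop ORFs laid
    head-to-tail on the forward strand with random intergenic filler sized so
    that coding length / genome length is about ``coding_fraction``.
    Returns ``(genome_dna, [(protein_id, protein_seq), ...])``; the protein
    FASTA matches the translated ORFs exactly.
    """
    if not repertoire:
        raise ValueError("repertoire must be non-empty")
    if not 0 < coding_fraction <= 1:
        raise ValueError(f"coding_fraction must be in (0, 1], got {coding_fraction}")
    lo, hi = protein_len_range
    rng = np.random.default_rng(seed)

    proteins: list[tuple[str, str]] = []
    orfs: list[str] = []
    k = 0
    for dom in sorted(repertoire):
        motif = vocabulary[dom]
        for _copy in range(repertoire[dom]):
            k += 1
            length = int(rng.integers(max(lo, len(motif) + 2), hi + 1))
            body = list(rng.choice(list(AA20), size=length - 1))
            pos = int(rng.integers(0, len(body) - len(motif) + 1))
            body[pos : pos + len(motif)] = list(motif)
            protein = "M" + "".join(body)
            orf = "ATG" + _reverse_translate(protein[1:], rng) + _STOPS[rng.integers(len(_STOPS))]
            proteins.append((f"{species_id}_p{k:04d}", protein))
            orfs.append(orf)

    coding_len = sum(len(o) for o in orfs)
    filler_total = int(round(coding_len * (1 / coding_fraction - 1)))
    cuts = np.sort(rng.integers(0, filler_total + 1, size=len(orfs)))
    gaps = np.diff(np.concatenate([[0], cuts, [filler_total]]))
    parts = []
    for orf, gap in zip(orfs, gaps[:-1]):
        parts.append("".join(rng.choice(list(DNA4), size=int(gap))))
        parts.append(orf)
    parts.append("".join(rng.choice(list(DNA4), size=int(gaps[-1]))))
    return "".join(parts), proteins


# ---------------------------------------------------------------------------
# Toy domain scanner
# ---------------------------------------------------------------------------

def toy_scan(
    peptides: Sequence[tuple[str, str]],
    vocabulary: Mapping[str, str],
) -> list[DomainHit]:
    """Exact-match motif scan: the deterministic stand-in for a domain search.

    One hit per (ungapped, case-insensitive) motif occurrence, with 1-based
    inclusive coordinates. Overlapping occurrences of different motifs are
    all reported; because no motif is a substring of another, at most one
    motif can start at any given position.
    """
    check_vocabulary(vocabulary)
    if not peptides:
        return []
    # scan one '#'-joined blob per motif: motifs are pure amino-acid strings,
    # so they cannot straddle the separator; positions map back by bisection
    ids = [pid for pid, _seq in peptides]
    seqs = [seq.upper() for _pid, seq in peptides]
    starts = np.zeros(len(seqs), dtype=np.int64)
    np.cumsum([len(s) + 1 for s in seqs[:-1]], out=starts[1:])
    blob = "#".join(seqs)
    found: list[tuple[int, str]] = []  # (blob position, domain id)
    for dom, motif in vocabulary.items():
        pos = blob.find(motif)
        while pos != -1:
            found.append((pos, dom))
            pos = blob.find(motif, pos + 1)
    hits: list[DomainHit] = []
    for pos, dom in sorted(found):
        idx = int(np.searchsorted(starts, pos, side="right") - 1)
        start = pos - int(starts[idx]) + 1
        hits.append(
            DomainHit(
                protein_id=ids[idx],
                domain_id=dom,
                domain_name=dom,
                start=start,
                end=start + len(vocabulary[dom]) - 1,
                protein_length=len(seqs[idx]),
                database="toyscan",
                evalue=0.0,
                matched=True,
            )
        )
    return hits


def scan_peptide_set(peptide_set, vocabulary: Mapping[str, str]) -> list[DomainHit]:
    """Scan a :class:`~domprof.read_sim.PeptideSet` (read/frame ids kept)."""
    records = [
        (f"{p.read_id}|frame={p.frame}|off={p.offset_aa}", p.sequence)
        for p in peptide_set.peptides
    ]
    return toy_scan(records, vocabulary)


# ---------------------------------------------------------------------------
# Marker evolution
# ---------------------------------------------------------------------------

def evolve_marker(
    tree: dendropy.Tree,
    length: int = 1200,
    sub_rate: float = 0.1,
    alphabet: str = "dna",
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Evolve a gap-free marker alignment on a tree.

    Symmetric (Jukes-Cantor-style) model: each site substitutes along a
    branch of length ``t`` with probability ``1 - exp(-sub_rate * t)``; the
    new state is uniform among the other states. Works for DNA (4 states)
    or protein (20 states).
    """
    if length < 100:
        raise ValueError("marker length must be >= 100")
    if sub_rate < 0:
        raise ValueError("sub_rate must be >= 0")
    states = DNA4 if alphabet == "dna" else AA20
    if alphabet not in ("dna", "protein"):
        raise ValueError(f"alphabet must be dna or protein, got {alphabet!r}")
    k = len(states)
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, k, size=length)

    out: dict[str, str] = {}

    def descend(node: dendropy.Node, seq: np.ndarray) -> None:
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            p_sub = 1 - math.exp(-sub_rate * t)
            mask = rng.random(length) < p_sub
            new_seq = seq.copy()
            if mask.any():
                shift = rng.integers(1, k, size=int(mask.sum()))
                new_seq[mask] = (new_seq[mask] + shift) % k
            if child.is_leaf():
                out[child.taxon.label] = "".join(states[i] for i in new_seq)
            else:
                descend(child, new_seq)

    descend(tree.seed_node, root_seq)
    return [(t.label, out[t.label]) for t in tree.taxon_namespace if t.label in out]


def calibrate_marker_rate(tree: dendropy.Tree, target_p: float = 0.1) -> float:
    """Substitution rate giving a mean pairwise p-distance near ``target_p``.

    Inverts the symmetric-model expectation p = (3/4)(1 - exp(-(4/3) r D))
    at the tree's mean patristic distance D (DNA alphabet).
    """
    if not 0 < target_p < 0.75:
        raise ValueError("target_p must be in (0, 0.75)")
    dm = patristic_distances(tree).values()
    n = dm.shape[0]
    mean_d = dm[np.triu_indices(n, k=1)].mean()
    return -math.log1p(-(4.0 / 3.0) * target_p) * 3.0 / (4.0 * mean_d)


# ---------------------------------------------------------------------------
# Whole-study bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic study: tree, motifs, repertoires, params."""

    tree: dendropy.Tree
    vocabulary: dict[str, str]
    repertoires: dict[str, Counter]
    params: dict = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return sorted(self.repertoires)


def simulate_study(
    n_leaves: int = 20,
    seed: int = 0,
    n_domains: int = 600,
    root_size: int = 150,
    gain_rate: float = 450.0,
    loss_rate: float = 3.0,
    copy_rate: float = 2.0,
    coding_fraction: float = 0.8,
) -> SyntheticTruth:
    """Simulate a full genome study: tree, vocabulary and leaf repertoires.

    The default rates keep the equilibrium repertoire near ``gain/loss`` =
    150 types while turning domains over fast enough that each species
    carries a minority (roughly 35-40%) of the domains seen across the
    study, matching the sparsity of real domain count matrices; the
    duplication rate gives the overdispersed copy numbers real profiles
    show.
    """
    tree = simulate_tree(n_leaves, seed=child_seed(seed, "tree"))
    vocabulary = make_vocabulary(n_domains, seed=child_seed(seed, "vocab"))
    repertoires = evolve_repertoires(
        tree,
        vocabulary,
        gain_rate=gain_rate,
        loss_rate=loss_rate,
        copy_rate=copy_rate,
        seed=child_seed(seed, "repertoires"),
        root_size=root_size,
    )
    params = dict(
        n_leaves=n_leaves,
        seed=seed,
        n_domains=n_domains,
        root_size=root_size,
        gain_rate=gain_rate,
        loss_rate=loss_rate,
        copy_rate=copy_rate,
        coding_fraction=coding_fraction,
    )
    return SyntheticTruth(tree=tree, vocabulary=vocabulary, repertoires=repertoires, params=params)


# ---------------------------------------------------------------------------
# Environmental communities
# ---------------------------------------------------------------------------

@dataclass
class EnvSample:
    """One planned environmental sample: covariates plus mixture weights."""

    metadata: SampleMetadata
    weights: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"mixture weights for {self.metadata.sample_id} sum to {total}, not 1"
            )


_COLD_MONTHS = (12, 1, 2, 3, 4)
_WARM_MONTHS = (5, 6, 7, 8, 9, 10, 11)


def design_pore_season(
    genome_ids: Sequence[str],
    samples_per_pore: int = 4,
    pores: Sequence[float] = (0.2, 0.8, 5.0),
    pore_effect: float = 0.9,
    season_effect: float = 0.0,
    season_pore: float = 0.8,
    seed: int = 0,
) -> list[EnvSample]:
    """Build a sampling design where composition follows pore size (and season).

    Genomes are split into one dominant set per pore class; a sample in pore
    class g puts ``pore_effect`` of its weight uniformly on g's set and the
    rest uniformly on all other genomes. When ``season_effect`` > 0, the
    dominant set of ``season_pore`` is further split into a cold-season and a
    warm-season half, and that fraction of the group weight moves to the half
    matching the sample's season. Depth class and station follow balanced
    patterns orthogonal to the season alternation (use a multiple of 4
    samples per pore class to keep them exactly balanced), so season is the
    only composition-driving factor besides pore size. The design itself is
    deterministic; ``seed`` is kept for interface symmetry with the other
    generators.
    """
    if len(genome_ids) < len(pores):
        raise ValueError("need at least one genome per pore class")
    del seed
    ids = list(genome_ids)
    groups: dict[float, list[str]] = {
        pore: ids[i :: len(pores)] for i, pore in enumerate(pores)
    }
    samples: list[EnvSample] = []
    for pore in pores:
        dominant = groups[pore]
        others = [g for g in ids if g not in dominant]
        cold_half = dominant[: max(1, len(dominant) // 2)]
        warm_half = [g for g in dominant if g not in cold_half] or dominant
        for i in range(samples_per_pore):
            cold = i % 2 == 0
            month = _COLD_MONTHS[i % len(_COLD_MONTHS)] if cold else _WARM_MONTHS[i % len(_WARM_MONTHS)]
            year = 2012 + (i // 12)
            meta = SampleMetadata(
                sample_id=f"S{pore}_{i + 1:02d}",
                collection_date=_dt.date(year, month, 15),
                filter_pore=pore,
                station=("bay", "offshore")[(i // 2) % 2],
                depth_class=("surface", "SCM")[i % 4 in (1, 2)],
            )
            weights = dict.fromkeys(ids, 0.0)
            group_w = pore_effect
            rest_w = 1.0 - pore_effect
            use_season = season_effect > 0 and pore == season_pore
            if use_season:
                favored = cold_half if cold else warm_half
                unfavored = warm_half if cold else cold_half
                for g in favored:
                    weights[g] += group_w * season_effect / len(favored)
                remaining = group_w * (1 - season_effect)
                for g in dominant:
                    weights[g] += remaining / len(dominant)
                del unfavored
            else:
                for g in dominant:
                    weights[g] += group_w / len(dominant)
            for g in others:
                weights[g] += rest_w / len(others)
            total = sum(weights.values())
            weights = {g: w / total for g, w in weights.items()}
            samples.append(EnvSample(metadata=meta, weights=weights))
    return samples


def simulate_environment(
    genome_pool: Mapping[str, str],
    design: Sequence[EnvSample],
    reads_per_sample: int = 8000,
    frag_len: int = 100,
    seed: int = 0,
) -> tuple[dict[str, list[str]], list[SampleMetadata], pd.DataFrame]:
    """Draw per-sample 100 bp reads from a genome mixture.

    Each read picks a source genome by the sample's weights, then a uniform
    start and strand. Returns (reads by sample, metadata, truth weights as a
    samples x genomes DataFrame).
    """
    from Bio.Seq import reverse_complement

    genome_ids = sorted(genome_pool)
    rng = np.random.default_rng(seed)
    reads_by_sample: dict[str, list[str]] = {}
    metadata: list[SampleMetadata] = []
    weight_rows = []
    for sample in design:
        missing = set(sample.weights) - set(genome_ids)
        if missing:
            raise ValueError(f"weights reference unknown genomes: {sorted(missing)}")
        w = np.array([sample.weights.get(g, 0.0) for g in genome_ids])
        sources = rng.choice(len(genome_ids), size=reads_per_sample, p=w)
        reads = []
        for src in sources:
            genome = genome_pool[genome_ids[src]]
            start = int(rng.integers(0, len(genome) - frag_len + 1))
            read = genome[start : start + frag_len]
            if rng.random() < 0.5:
                read = reverse_complement(read)
            reads.append(read)
        reads_by_sample[sample.metadata.sample_id] = reads
        metadata.append(sample.metadata)
        weight_rows.append([sample.weights.get(g, 0.0) for g in genome_ids])
    truth = pd.DataFrame(
        weight_rows,
        index=[s.metadata.sample_id for s in design],
        columns=genome_ids,
    )
    return reads_by_sample, metadata, truth
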