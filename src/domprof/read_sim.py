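"""Short-read simulation and six-frame translation.

Emulates shotgun sequencing at the matrix level: fixed-length fragments are
cut uniformly at random from a genome so that their total length is a chosen
multiple of the genome length, then each fragment is translated in all six
reading frames and split at stop codons into maximal stop-free peptides.
Downstream, those peptides are scanned for domains exactly like full
proteins.

Two length filters are used in practice: a permissive one (default 8 aa,
enough to contain a motif) for the genome-fragment benchmark, and 30 aa for
the environmental workflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import reverse_complement

logger = logging.getLogger(__name__)

FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)


@dataclass
class Fragment:
    start: int  # 0-based position on the source genome (forward strand)
    strand: str  # "+" or "-"
    sequence: str


@dataclass
class FragmentSet:
    source_id: str
    fragment_length: int
    fragments: list[Fragment]

    def __len__(self) -> int:
        return len(self.fragments)


@dataclass
class Peptide:
    read_id: str
    frame: str  # one of FRAMES
    offset_aa: int  # 0-based start of the peptide within its frame translation
    sequence: str

    def __post_init__(self) -> None:
        if "*" in self.sequence:
            raise ValueError("peptides must be stop-free")


@dataclass
class PeptideSet:
    peptides: list[Peptide] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peptides)

    def by_frame(self) -> dict[str, int]:
        counts = {f: 0 for f in FRAMES}
        for p in self.peptides:
            counts[p.frame] += 1
        return counts


def sample_fragments(
    genome: str,
    frag_len: int = 100,
    depth_multiple: float = 10.0,
    seed: int | np.random.Generator = 0,
    source_id: str = "genome",
    both_strands: bool = True,
    with_replacement: bool = True,
) -> FragmentSet:
    """Cut ``round(depth_multiple * L / frag_len)`` fragments from a genome.

    Start positions are uniform on [0, L - frag_len]; strands are uniform
    when ``both_strands``. The genome is treated as linear (fragments never
    wrap the origin).
    """
    L = len(genome)
    if L < frag_len:
        raise ValueError(f"genome length {L} shorter than fragment length {frag_len}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = round(depth_multiple * L / frag_len)
    starts = rng.integers(0, L - frag_len + 1, size=n)
    if not with_replacement:
        starts = np.unique(starts)
    strands = rng.choice(["+", "-"], size=len(starts)) if both_strands else ["+"] * len(starts)
    fragments = []
    for s, strand in zip(starts, strands):
        seq = genome[s : s + frag_len]
        if strand == "-":
            seq = reverse_complement(seq)
        fragments.append(Fragment(start=int(s), strand=strand, sequence=seq))
    return FragmentSet(source_id=source_id, fragment_length=frag_len, fragments=fragments)


def _translate_frame(dna: str) -> str:
    aas = []
    for i in range(0, len(dna) - 2, 3):
        codon = dna[i : i + 3]
        if codon in _STOP_CODONS:
            aas.append("*")
        else:
            aas.append(_CODON_TABLE.get(codon, "X"))  # codons with N/unknown -> X
    return "".join(aas)


def six_frame_translate(fragment_dna: str, read_id: str = "read", min_len: int = 1) -> PeptideSet:
    """Translate a DNA fragment in all six frames, splitting at stop codons.

    Frames +1/+2/+3 read the forward strand at offsets 0/1/2; -1/-2/-3 read
    the reverse complement the same way. Each frame is split at stops into
    maximal stop-free peptides; pieces shorter than ``min_len`` are dropped
    (the default keeps everything).
    """
    seq = fragment_dna.upper()
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - set("ACGTN"):
        raise ValueError(f"non-DNA characters in sequence: {sorted(set(seq) - set('ACGTN'))}")
    rc = reverse_complement(seq)
    peptides: list[Peptide] = []
    for strand, template in (("+", seq), ("-", rc)):
        for off in range(3):
            frame = f"{strand}{off + 1}"
            aa = _translate_frame(template[off:])
            pos = 0
            for piece in aa.split("*"):
                if len(piece) >= min_len and piece:
                    peptides.append(
                        Peptide(read_id=read_id, frame=frame, offset_aa=pos, sequence=piece)
                    )
                pos += len(piece) + 1
    return PeptideSet(peptides)


def translate_fragments(
    fragments: FragmentSet, min_len: int = 8, read_prefix: str | None = None
) -> PeptideSet:
    """Six-frame translate every fragment of a set into one peptide pool."""
    prefix = read_prefix if read_prefix is not None else fragments.source_id
    pool: list[Peptide] = []
    for i, frag in enumerate(fragments.fragments):
        ps = six_frame_translate(frag.sequence, read_id=f"{prefix}_{i}", min_len=min_len)
        pool.extend(ps.peptides)
    return PeptideSet(pool)


def filter_peptides(peptides: PeptideSet, min_len: int = 30) -> PeptideSet:
    """Keep peptides of at least ``min_len`` residues; log per-frame counts."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = PeptideSet([p for p in peptides.peptides if len(p.sequence) >= min_len])
    logger.debug("peptide filter >=%d aa: kept %d/%d; per frame %s",
                 min_len, len(kept), len(peptides), kept.by_frame())
    return kept


def subsample_reads(
    reads: Sequence, n: int = 500_000, seed: int | np.random.Generator = 0
) -> list:
    """Uniform subsample without replacement; returns all reads when n exceeds the pool."""
    if n < 0:
        raise ValueError("n must be >= 0")
    reads = list(reads)
    if n >= len(reads):
        if n > len(reads):
            logger.warning("requested %d reads but only %d available; returning all", n, len(reads))
        return reads
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=n, replace=False)
    return [reads[i] for i in sorted(idx)]
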