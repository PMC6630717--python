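"""Convenience compositions of the pipeline stages.

These helpers wire the per-stage operations together for the two common
workflows: profiling whole proteomes, and profiling pools of short reads
(six-frame translation, length filter, motif scan, tally).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .containers import DomainCountMatrix
from .domain_matrix import count_domains
from .read_sim import filter_peptides, six_frame_translate
from .synthetic_data import toy_scan


def domain_profile_from_proteins(
    proteins_by_sample: Mapping[str, Sequence[tuple[str, str]]],
    vocabulary: Mapping[str, str],
) -> DomainCountMatrix:
    """Raw domain count matrix from per-sample protein sets (toy scanner)."""
    hits = {s: toy_scan(prots, vocabulary) for s, prots in proteins_by_sample.items()}
    return count_domains(hits)


def domain_profile_from_reads(
    reads_by_sample: Mapping[str, Iterable[str]],
    vocabulary: Mapping[str, str],
    min_peptide_len: int = 8,
) -> DomainCountMatrix:
    """Raw domain count matrix from per-sample DNA read pools.

    Each read is translated in six frames, split at stops, filtered to
    ``min_peptide_len`` residues (use 30 for the environmental convention)
    and scanned for motifs; counts are tallied per sample.
    """
    hits = {}
    for sample, reads in reads_by_sample.items():
        peptides = []
        for i, read in enumerate(reads):
            ps = six_frame_translate(read, read_id=f"{sample}_{i}", min_len=1)
            ps = filter_peptides(ps, min_len=min_peptide_len)
            peptides.extend(
                (f"{p.read_id}|frame={p.frame}|off={p.offset_aa}", p.sequence)
                for p in ps.peptides
            )
        hits[sample] = toy_scan(peptides, vocabulary)
    return count_domains(hits)
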