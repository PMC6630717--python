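"""Coding-region ratio and the species-level completeness filter.

A proteome that fails to cover most of its genome signals missing protein
records (the ratio would be far below 100%); such species are excluded
before any domain profiling.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

logger = logging.getLogger(__name__)

#: Default exclusion threshold in percent. Complete bacterial proteomes sit
#: around 70-90% coding; incomplete protein sets fall to single digits. 50%
#: separates the regimes with margin on both sides.
DEFAULT_MIN_RATIO = 50.0


def coding_ratio(protein_lengths: Sequence[int], genome_length: int) -> float:
    """Percent of the genome covered by coding sequence.

    ``(sum of protein lengths in aa) * 3 / genome length in bp * 100``.
    Values above 100% are arithmetically possible (overlapping ORFs) and are
    logged as a warning rather than rejected.
    """
    if genome_length <= 0:
        raise ValueError(f"genome length must be positive, got {genome_length}")
    if any(l < 0 for l in protein_lengths):
        raise ValueError("protein lengths must be non-negative")
    ratio = sum(protein_lengths) * 3 / genome_length * 100
    if ratio > 100:
        logger.warning("coding ratio %.2f%% exceeds 100%% (overlapping ORFs?)", ratio)
    return ratio


def filter_species(
    ratios: Mapping[str, float], min_ratio: float = DEFAULT_MIN_RATIO
) -> tuple[dict[str, float], dict[str, float]]:
    """Partition species into (kept, excluded) by coding-ratio threshold."""
    if not ratios:
        raise ValueError("ratios must be non-empty")
    kept = {s: r for s, r in ratios.items() if r >= min_ratio}
    excluded = {s: r for s, r in ratios.items() if r < min_ratio}
    if not kept:
        logger.warning("all %d species fall below min_ratio=%s%%", len(ratios), min_ratio)
    return kept, excluded
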