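"""Pairwise genetic distances from aligned marker genes.

Replaces the usual phylogenetics-suite pairwise-distance step for marker
genes such as 16S rRNA (DNA) and gyrB (DNA or protein). Inputs must already
be aligned; only distances are computed, never trees.

Models:

* ``p`` — proportion of differing sites (assumption-free; the default);
* ``jukes_cantor`` — DNA correction -(3/4) ln(1 - (4/3) p);
* ``poisson_aa`` — protein correction -ln(1 - p).

Gap and ambiguity characters are skipped pairwise (pairwise deletion).
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import DistanceMatrix

logger = logging.getLogger(__name__)

#: characters ignored during site comparison (gaps and ambiguity codes)
SKIP_CHARS = set("-.NXnx?")


def dedup_and_length_filter(
    sequences: Sequence[tuple[str, str]],
    min_len_fraction: float = 0.5,
    policy: str = "drop_all",
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], dict[str, str]]:
    """Remove too-short and duplicate marker sequences before distance work.

    Length is measured on non-gap characters against the median. Groups of
    byte-identical sequences are either removed entirely (``drop_all``, the
    default — identical markers carry no pairwise signal and typically flag a
    database artefact) or collapsed to their first member (``keep_one``).
    Returns (kept, removed, reasons-by-id).
    """
    if not sequences:
        raise ValueError("sequences must be non-empty")
    if policy not in ("drop_all", "keep_one"):
        raise ValueError(f"policy must be drop_all or keep_one, got {policy!r}")
    lengths = [sum(1 for c in seq if c not in SKIP_CHARS) for _id, seq in sequences]
    median = float(np.median(lengths))
    reasons: dict[str, str] = {}

    survivors = []
    for (sid, seq), length in zip(sequences, lengths):
        if length < min_len_fraction * median:
            reasons[sid] = "short"
        else:
            survivors.append((sid, seq))

    groups: dict[str, list[str]] = {}
    for sid, seq in survivors:
        groups.setdefault(seq, []).append(sid)
    kept: list[tuple[str, str]] = []
    for sid, seq in survivors:
        members = groups[seq]
        if len(members) > 1:
            if policy == "drop_all" or sid != members[0]:
                reasons[sid] = "duplicate"
                continue
        kept.append((sid, seq))

    removed = [(sid, seq) for sid, seq in sequences if sid in reasons]
    if removed:
        logger.info("marker filter removed %d sequence(s): %s", len(removed), reasons)
    return kept, removed, reasons


def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of differing sites under pairwise deletion.

    Sites where either sequence has a gap or ambiguity character are skipped;
    NaN (with a warning) when no comparable sites remain.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(f"sequences must be aligned: lengths {len(seq_a)} != {len(seq_b)}")
    compared = 0
    diff = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in SKIP_CHARS or b in SKIP_CHARS:
            continue
        compared += 1
        if a != b:
            diff += 1
    if compared == 0:
        logger.warning("no comparable sites between sequences; distance undefined")
        return math.nan
    return diff / compared


def jc_distance(p: float) -> float:
    """Jukes-Cantor DNA distance -(3/4) ln(1 - (4/3) p); +inf at saturation."""
    if math.isnan(p):
        return math.nan
    if not 0 <= p:
        raise ValueError(f"p must be >= 0, got {p}")
    if p >= 0.75:
        logger.warning("p-distance %.3f at or beyond JC saturation (0.75)", p)
        return math.inf
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def poisson_aa_distance(p: float) -> float:
    """Poisson-corrected amino-acid distance -ln(1 - p); +inf at p = 1."""
    if math.isnan(p):
        return math.nan
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if p == 1:
        logger.warning("p-distance 1.0: Poisson correction diverges")
        return math.inf
    return -math.log1p(-p)


_MODELS = ("p", "jukes_cantor", "poisson_aa")


def all_pairs_distance(
    alignment: Sequence[tuple[str, str]], model: str = "p"
) -> DistanceMatrix:
    """Distance matrix over every unordered pair of aligned sequences."""
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}, got {model!r}")
    if len(alignment) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [sid for sid, _ in alignment]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in alignment")
    n = len(alignment)
    values = np.zeros((n, n))
    nan_pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(alignment[i][1], alignment[j][1])
            if model == "jukes_cantor":
                d = jc_distance(p)
            elif model == "poisson_aa":
                d = poisson_aa_distance(p)
            else:
                d = p
            values[i, j] = values[j, i] = d
            if math.isnan(d):
                nan_pairs.append((ids[i], ids[j]))
    if nan_pairs:
        logger.warning("%d pair(s) have undefined distances: %s", len(nan_pairs), nan_pairs)
    return DistanceMatrix(pd.DataFrame(values, index=ids, columns=ids), model=model)
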