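"""Sequence-derived feature vectors for the cross-species view.

The cross-species view represents each protein by features computable from
sequence alone: a transformed BLAST hit profile against a database of
annotated proteins, 3-mer composition of the N- and C-terminal segments,
the amino-acid composition of the lowest-complexity window, and one-hot
encodings of externally predicted counts (e.g. transmembrane domains from
TMHMM).  Prediction tools themselves (BLAST, TMHMM, WoLF PSORT) are not run
here — their tabular outputs are ingested.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ValidationError

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: BLAST e-value handling: hits above the cutoff are discarded, the rest are
#: divided by the cutoff, floored, and negative-log10 transformed, giving
#: features in [0, 10].
BLAST_EVALUE_CUTOFF = 50.0
BLAST_FLOOR = 1e-10


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence (uppercase; nonstandard residues allowed)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"protein {self.id!r} has an empty sequence")
        if self.residues != self.residues.upper():
            raise ValidationError(f"protein {self.id!r}: residues must be uppercase")

    def __len__(self) -> int:
        return len(self.residues)


def pick_longest_isoform(sequences: Sequence[ProteinSequence]) -> ProteinSequence:
    """The longest isoform of a gene; ties go to the lexicographically
    smallest id."""
    if not sequences:
        raise ValidationError("no sequences given")
    return sorted(sequences, key=lambda s: (-len(s), s.id))[0]


def blast_feature_transform(hits: Mapping[str, float]) -> dict[str, float]:
    """Transform BLAST e-values into similarity features.

    Hits with e-value above 50.0 are excluded (feature absent, i.e. 0);
    remaining e-values are divided by 50.0, brought up to 1e-10 if smaller,
    and negative-log10 transformed.  All features lie in [0, 10] and smaller
    e-values give larger features.
    """
    out: dict[str, float] = {}
    for target, e in hits.items():
        if e < 0:
            raise ValidationError(f"negative e-value {e!r} for hit {target!r}")
        if e > BLAST_EVALUE_CUTOFF:
            continue
        scaled = max(e / BLAST_EVALUE_CUTOFF, BLAST_FLOOR)
        out[target] = -math.log10(scaled)
    return out


def blast_feature_table(
    hits_by_query: Mapping[str, Mapping[str, float]],
    targets: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Feature table over the target database from per-query BLAST hits."""
    rows = {q: blast_feature_transform(h) for q, h in hits_by_query.items()}
    frame = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    if targets is not None:
        frame = frame.reindex(columns=list(targets), fill_value=0.0)
    return frame.sort_index(axis=1) if targets is None else frame


def termini_kmer_composition(
    seq: ProteinSequence, k: int = 3, segment_length: int = 10
) -> dict[str, int]:
    """k-mer counts of the N- and C-terminal segments.

    Two count blocks are returned with key prefixes ``nterm:`` and
    ``cterm:``.  Sequences shorter than ``segment_length`` use the whole
    sequence for both blocks; sequences shorter than ``k`` yield an empty
    (all-zero) vector, logged.
    """
    if k > segment_length:
        raise ValidationError(f"k={k} exceeds segment_length={segment_length}")
    s = seq.residues
    if k > len(s):
        logger.info(
            "termini_kmer_composition: %r shorter than k=%d, zero vector",
            seq.id, k,
        )
        return {}
    n_seg = s[:segment_length] if len(s) >= segment_length else s
    c_seg = s[-segment_length:] if len(s) >= segment_length else s
    counts: dict[str, int] = {}
    for prefix, segment in (("nterm", n_seg), ("cterm", c_seg)):
        for i in range(len(segment) - k + 1):
            key = f"{prefix}:{segment[i:i + k]}"
            counts[key] = counts.get(key, 0) + 1
    return counts


def low_complexity_composition(
    seq: ProteinSequence, window: int = 20
) -> dict[str, int]:
    """Amino-acid composition of the lowest-complexity window.

    Scans all windows of length ``window`` and keeps the one with the fewest
    distinct residues (leftmost on ties); returns its residue counts.
    Sequences shorter than ``window`` use the whole sequence.  Nonstandard
    residues count as distinct symbols.
    """
    s = seq.residues
    if len(s) <= window:
        return dict(Counter(s))
    best_start = 0
    best_distinct = window + 1
    counts = Counter(s[:window])
    best_counts = dict(counts)
    distinct = len(counts)
    if distinct < best_distinct:
        best_distinct = distinct
    for start in range(1, len(s) - window + 1):
        out_res, in_res = s[start - 1], s[start + window - 1]
        counts[out_res] -= 1
        if counts[out_res] == 0:
            del counts[out_res]
        counts[in_res] += 1
        if len(counts) < best_distinct:
            best_distinct = len(counts)
            best_start = start
            best_counts = dict(counts)
    return best_counts


def count_indicator(count: int, max_count: int) -> np.ndarray:
    """One-hot encode a non-negative count into ``max_count + 1`` bins.

    Counts above ``max_count`` collapse into the last bin (logged); used
    e.g. for the number of predicted transmembrane domains.
    """
    if max_count < 0:
        raise ValidationError("max_count must be non-negative")
    if count < 0:
        raise ValidationError(f"negative count {count!r}")
    vec = np.zeros(max_count + 1)
    if count > max_count:
        logger.info("count_indicator: count %d clamped to %d", count, max_count)
        count = max_count
    vec[count] = 1.0
    return vec


def count_indicator_table(
    counts: Mapping[str, int], max_count: int, prefix: str = "count"
) -> pd.DataFrame:
    """One-hot table over proteins from a protein → count mapping."""
    data = {pid: count_indicator(c, max_count) for pid, c in counts.items()}
    cols = [f"{prefix}:{i}" for i in range(max_count + 1)]
    return pd.DataFrame.from_dict(data, orient="index").set_axis(cols, axis=1)


def features_to_frame(
    per_protein: Mapping[str, Mapping[str, float]]
) -> pd.DataFrame:
    """Assemble sparse per-protein feature dicts into a dense table."""
    frame = pd.DataFrame.from_dict(dict(per_protein), orient="index").fillna(0.0)
    return frame.reindex(sorted(frame.columns), axis=1)


# -- readers -----------------------------------------------------------------


def read_fasta(path) -> list[ProteinSequence]:
    return [
        ProteinSequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_blast_tab(path) -> dict[str, dict[str, float]]:
    """Read BLAST tabular output (outfmt 6); keeps the best e-value per pair."""
    hits: dict[str, dict[str, float]] = {}
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 11:
        raise ValidationError(
            f"{path}: expected ≥11 tab-separated BLAST columns, "
            f"got {df.shape[1]}"
        )
    for query, target, evalue in zip(df[0], df[1], pd.to_numeric(df[10])):
        row = hits.setdefault(str(query), {})
        e = float(evalue)
        if str(target) not in row or e < row[str(target)]:
            row[str(target)] = e
    return hits
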