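"""Entropy-based oligotype decomposition of aligned amplicon reads.

An oligotype is the concatenation of a read's residues at the k
highest-Shannon-entropy columns of the alignment (k = 2 by default, matching
the common choice for the V3–V4 region).  Gaps and ambiguity codes are kept
as ordinary characters: dropping them would silently change counts.  A
single round of component selection is performed — oligotypes are not
recursively re-decomposed to purity.

Reads are assigned to samples either through an explicit read→sample
mapping, or by the ``<sample>_<serial>`` identifier convention (split on
the last underscore).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "EntropyProfile",
    "OligotypeTable",
    "read_alignment",
    "sample_from_read_id",
    "column_entropy",
    "entropy_profile",
    "select_components",
    "decompose",
    "write_matrix_percent",
]


@dataclass
class EntropyProfile:
    """Per-column Shannon entropy (bits) of an alignment."""

    entropy: np.ndarray
    counts: list[Counter]

    @property
    def alignment_length(self) -> int:
        return len(self.entropy)

    def __post_init__(self) -> None:
        self.entropy = np.asarray(self.entropy, dtype=float)
        if (self.entropy < -1e-12).any():
            raise ValueError("entropy must be non-negative")
        if len(self.counts) != len(self.entropy):
            raise ValueError("counts/entropy length mismatch")


@dataclass
class OligotypeTable:
    """Oligotype × sample counts and percents at selected columns."""

    positions: list[int]
    counts: pd.DataFrame  # oligotype × sample, integer reads
    percents: pd.DataFrame  # oligotype × sample, 0–100

    @property
    def oligotypes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def read_alignment(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA file as (identifier, sequence) pairs.

    All sequences must be the same length; the offending record is named
    otherwise.
    """
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"{path}: no sequences")
    length = len(records[0][1])
    for rid, seq in records:
        if len(seq) != length:
            raise ValueError(
                f"ragged alignment: read {rid!r} has length {len(seq)}, expected {length}"
            )
    return records


def sample_from_read_id(read_id: str) -> str:
    """Sample name from a ``<sample>_<serial>`` read identifier."""
    if "_" not in read_id:
        raise ValueError(
            f"cannot infer sample from read id {read_id!r} (no underscore); "
            "provide an explicit read→sample mapping"
        )
    return read_id.rsplit("_", 1)[0]


def column_entropy(column: Mapping[str, int] | Iterable[str]) -> float:
    """Shannon entropy, in bits, of one alignment column.

    H = −Σ_c p_c log2 p_c over the characters observed in the column.
    """
    counts = column if isinstance(column, Mapping) else Counter(column)
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("empty column")
    p = np.array([c for c in counts.values() if c > 0], dtype=float) / total
    return float(-(p * np.log2(p)).sum())


def entropy_profile(alignment: Sequence[tuple[str, str]]) -> EntropyProfile:
    """Per-column entropy over all reads pooled across samples."""
    if not alignment:
        raise ValueError("empty alignment")
    length = len(alignment[0][1])
    for rid, seq in alignment:
        if len(seq) != length:
            raise ValueError(f"ragged alignment: read {rid!r} has length {len(seq)}")
    chars = np.array([list(seq) for _, seq in alignment])
    counts = [Counter(chars[:, j]) for j in range(length)]
    entropy = np.array([column_entropy(c) for c in counts])
    return EntropyProfile(entropy=entropy, counts=counts)


def select_components(profile: EntropyProfile, k: int = 2) -> list[int]:
    """Indices of the k highest-entropy columns, ascending.

    Ties are broken toward the smaller column index.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > profile.alignment_length:
        raise ValueError(
            f"k={k} exceeds alignment length {profile.alignment_length}"
        )
    order = sorted(range(profile.alignment_length), key=lambda i: (-profile.entropy[i], i))
    return sorted(order[:k])


def decompose(
    alignment: Sequence[tuple[str, str]],
    positions: Sequence[int],
    sample_of: Mapping[str, str] | None = None,
) -> OligotypeTable:
    """Assign each read its oligotype label and tabulate per-sample counts.

    No minimum-abundance or minimum-sample filtering is applied: every
    observed oligotype is retained.  Oligotypes are ordered by descending
    total count, ties alphabetical.
    """
    if not positions:
        raise ValueError("positions must be non-empty")
    length = len(alignment[0][1]) if alignment else 0
    for p in positions:
        if not 0 <= p < length:
            raise ValueError(f"position {p} outside alignment of length {length}")
    tallies: dict[str, Counter] = {}
    for rid, seq in alignment:
        if sample_of is not None:
            if rid not in sample_of:
                raise KeyError(f"read {rid!r} absent from the sample mapping")
            sample = sample_of[rid]
        else:
            sample = sample_from_read_id(rid)
        label = "".join(seq[p] for p in positions)
        tallies.setdefault(sample, Counter())[label] += 1

    samples = list(tallies)
    oligos = sorted({o for c in tallies.values() for o in c})
    counts = pd.DataFrame(
        {s: [tallies[s].get(o, 0) for o in oligos] for s in samples},
        index=oligos,
        dtype=np.int64,
    )
    order = counts.sum(axis=1).sort_values(ascending=False, kind="stable")
    # stable sort on descending totals keeps the alphabetical pre-order for ties
    counts = counts.loc[order.index]
    totals = counts.sum(axis=0)
    percents = 100.0 * counts / totals.replace(0, np.nan)
    return OligotypeTable(positions=sorted(positions), counts=counts, percents=percents.fillna(0.0))


def write_matrix_percent(table: OligotypeTable, path: str | Path) -> None:
    """Write the oligotyping ``matrix_percents.txt`` dialect."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(["samples", *table.oligotypes]) + "\n")
        for sample in table.samples:
            vals = [f"{v:.6f}" for v in table.percents[sample]]
            fh.write("\t".join([sample, *vals]) + "\n")
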