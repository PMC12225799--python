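"""Mutation-tolerance profiling of a structure-based alignment.

The workflow mirrors the conservation stage of the pipeline: drop
alignment columns with 10% or more gaps, compute the per-column Shannon
entropy in bits over the non-gap residues, and pull out the handful of
low-entropy "core" positions for a separate phylogenetic analysis.  An
invariant column scores 0 bits; a column sampling all 20 amino acids
uniformly scores log2(20) ≈ 4.32 bits.  Gaps carry no probability mass:
columns are pre-filtered to be nearly gap-free, and excluding gaps keeps
alignment coverage from masquerading as sequence variability.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import AllGapColumnError, InvalidParameterError, UnderdeterminedError
from .structure_io import GAP, Msa

#: Default maximum per-column gap fraction; columns at or above it are dropped.
DEFAULT_MAX_GAP_FRACTION = 0.10


def filter_columns(
    msa: Msa, max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION
) -> tuple[Msa, list[int]]:
    """Retain columns whose gap fraction is strictly below the threshold.

    Returns the filtered alignment and the map from filtered column
    index to original column index.  If every column is removed the
    result is an empty (zero-width) alignment and a warning is emitted.
    """
    if msa.n_taxa == 0:
        raise InvalidParameterError("empty alignment")
    arr = msa.to_array()
    gap_fraction = (arr == GAP).mean(axis=0)
    keep = [j for j in range(msa.width) if gap_fraction[j] < max_gap_fraction]
    if not keep and msa.width > 0:
        warnings.warn("gap filter removed every alignment column", stacklevel=2)
    rows = tuple("".join(row[j] for j in keep) for row in msa.rows)
    return Msa(taxa=msa.taxa, rows=rows), keep


def shannon_entropy(column: Iterable[str]) -> float:
    """Shannon entropy of one alignment column, in bits.

    ``H = −Σ_a p_a log2 p_a`` with ``p_a`` the frequency of amino acid
    ``a`` among the non-gap symbols of the column.  A column with no
    non-gap residue has no defined entropy and raises
    :class:`AllGapColumnError`.
    """
    counts = Counter(c for c in column if c != GAP)
    total = sum(counts.values())
    if total == 0:
        raise AllGapColumnError("entropy undefined for an all-gap column")
    return -sum((n / total) * math.log2(n / total) for n in counts.values()) + 0.0


@dataclass(frozen=True)
class EntropyProfile:
    """Per-column conservation record of a (possibly filtered) alignment."""

    column_index: int           # index into the profiled alignment
    original_column_index: int  # index into the unfiltered alignment
    gap_fraction: float
    n_effective: int            # non-gap residues in the column
    entropy: float              # bits


def entropy_profile(
    msa: Msa, original_indices: Sequence[int] | None = None
) -> list[EntropyProfile]:
    """One entropy record per column, in column order.

    ``original_indices`` is the index map produced by
    :func:`filter_columns`; by default columns are their own original
    indices.  An all-gap column aborts with its index in the message.
    """
    if original_indices is None:
        original_indices = range(msa.width)
    if len(list(original_indices)) != msa.width:
        raise InvalidParameterError("index map length does not match alignment width")
    original_indices = list(original_indices)
    profile: list[EntropyProfile] = []
    for j in range(msa.width):
        col = msa.column(j)
        n_eff = sum(1 for c in col if c != GAP)
        try:
            h = shannon_entropy(col)
        except AllGapColumnError:
            raise AllGapColumnError(
                f"column {j} (original {original_indices[j]}) is all-gap"
            ) from None
        profile.append(
            EntropyProfile(
                column_index=j,
                original_column_index=original_indices[j],
                gap_fraction=(msa.n_taxa - n_eff) / msa.n_taxa,
                n_effective=n_eff,
                entropy=h,
            )
        )
    return profile


def low_entropy_positions(
    profile: Sequence[EntropyProfile], mode: str = "bottom_k", value: float = 9
) -> set[int]:
    """Select low-entropy columns; returns *original* column indices.

    ``mode="threshold"`` keeps columns with entropy ≤ ``value``;
    ``mode="bottom_k"`` keeps the ``value`` smallest entropies, breaking
    ties deterministically by lower original column index.
    """
    if not profile:
        raise InvalidParameterError("empty entropy profile")
    if mode == "threshold":
        return {p.original_column_index for p in profile if p.entropy <= value}
    if mode == "bottom_k":
        k = int(value)
        if k > len(profile):
            raise InvalidParameterError(
                f"k={k} exceeds the number of profiled columns ({len(profile)})"
            )
        ranked = sorted(profile, key=lambda p: (p.entropy, p.original_column_index))
        return {p.original_column_index for p in ranked[:k]}
    raise InvalidParameterError(f"unknown selection mode {mode!r}")


def extract_subalignment(msa: Msa, positions: Iterable[int]) -> Msa:
    """Slice an alignment down to the given columns, ascending order.

    Positions index into ``msa`` (use the filtered alignment together
    with filtered-frame positions, or the raw alignment with original
    positions).  An empty position set yields a zero-width alignment and
    a warning.
    """
    cols = sorted(set(positions))
    for p in cols:
        if not (0 <= p < msa.width):
            raise InvalidParameterError(
                f"column {p} out of range for width-{msa.width} alignment"
            )
    if not cols:
        warnings.warn("extracting an empty column set: zero-width alignment", stacklevel=2)
    rows = tuple("".join(row[j] for j in cols) for row in msa.rows)
    return Msa(taxa=msa.taxa, rows=rows)


def pairwise_identity(msa: Msa) -> np.ndarray:
    """Pairwise sequence identity over mutually non-gap columns.

    Returns an (n, n) symmetric matrix with unit diagonal; a pair with
    no comparable column is NaN.
    """
    if msa.n_taxa < 2:
        raise UnderdeterminedError("identity matrix needs at least 2 sequences")
    arr = msa.to_array()
    nongap = arr != GAP
    n = msa.n_taxa
    ident = np.ones((n, n))
    for i in range(n):
        both = nongap[i] & nongap[i + 1:]
        comparable = both.sum(axis=1)
        matches = ((arr[i] == arr[i + 1:]) & both).sum(axis=1)
        with np.errstate(invalid="ignore"):
            vals = np.where(comparable > 0, matches / np.maximum(comparable, 1), np.nan)
        ident[i, i + 1:] = vals
        ident[i + 1:, i] = vals
    return ident


def write_entropy_profile(profile: Sequence[EntropyProfile], path: str | Path) -> None:
    """Tab-separated profile: original_column, gap_fraction, n_effective, entropy_bits."""
    with open(path, "w") as handle:
        handle.write("original_column\tgap_fraction\tn_effective\tentropy_bits\n")
        for p in profile:
            handle.write(
                f"{p.original_column_index}\t{p.gap_fraction:.4f}\t"
                f"{p.n_effective}\t{p.entropy:.6f}\n"
            )


def write_positions(positions: Iterable[int], path: str | Path) -> None:
    """One 0-based column index per line, ascending."""
    with open(path, "w") as handle:
        for p in sorted(set(positions)):
            handle.write(f"{p}\n")
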