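"""The two-iteration hit-filtering cascade and its summary analyses.

The fold-mining workflow filters structure-search hits twice: a strict
first pass against an experimental-structure search (rmsd strictly below
2.0 Å and query coverage of at least 80%) to suppress false positives,
and a relaxed second pass against a predicted-structure search (rmsd
strictly below 3.0 Å and coverage of at least 30%) to admit multi-domain
proteins whose trefoil domain covers only part of the query.  Rmsd is
compared strictly, coverage inclusively — matching the executable
filters, where the boundary row at exactly 30% coverage is kept.

Also here: the kingdom-diversity summary of the retained hits, the
rmsd-versus-identity profile with its Spearman rank correlation and
step-pattern detector, and the one-representative-per-architecture
selection feeding the second search iteration.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .architecture import DomainArchitecture, architecture_signature
from .errors import InvalidParameterError
from .structure_io import KINGDOMS, SearchHit


@dataclass(frozen=True)
class FilterPreset:
    """Thresholds of one filtering iteration."""

    name: str
    rmsd_max: float      # Å, compared strictly (<)
    coverage_min: float  # fraction of the query length, compared inclusively (>=)

    def __post_init__(self):
        if self.rmsd_max <= 0:
            raise InvalidParameterError("rmsd_max must be positive")
        if not (0 < self.coverage_min <= 1):
            raise InvalidParameterError("coverage_min must be in (0, 1]")


ITERATION1 = FilterPreset("iteration1", rmsd_max=2.0, coverage_min=0.80)
ITERATION2 = FilterPreset("iteration2", rmsd_max=3.0, coverage_min=0.30)

_PRESETS = {p.name: p for p in (ITERATION1, ITERATION2)}


def preset(name: str) -> FilterPreset:
    try:
        return _PRESETS[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown preset {name!r}; expected one of {sorted(_PRESETS)}"
        ) from None


@dataclass
class FilterReport:
    """Count conservation record of one filtering pass."""

    n_input: int = 0
    n_kept: int = 0
    n_rejected: int = 0
    reasons: Counter = field(default_factory=Counter)
    data_errors: list[str] = field(default_factory=list)


def hit_passes(hit: SearchHit, p: FilterPreset) -> bool:
    """The filter predicate: rmsd strictly below, coverage at or above."""
    return hit.rmsd < p.rmsd_max and hit.coverage >= p.coverage_min


def filter_hits(
    hits: Sequence[SearchHit], p: FilterPreset
) -> tuple[list[SearchHit], FilterReport]:
    """Apply one filtering iteration; counts conserve (kept + rejected = input).

    Rows with a non-positive query length are data errors: rejected,
    reported, never raised.
    """
    report = FilterReport(n_input=len(hits))
    kept: list[SearchHit] = []
    for h in hits:
        if h.query_length <= 0:
            report.n_rejected += 1
            report.reasons["data_error"] += 1
            report.data_errors.append(
                f"{h.target_id}: non-positive query length {h.query_length}"
            )
            continue
        if h.rmsd >= p.rmsd_max:
            report.n_rejected += 1
            report.reasons["rmsd"] += 1
        elif h.coverage < p.coverage_min:
            report.n_rejected += 1
            report.reasons["coverage"] += 1
        else:
            kept.append(h)
            report.n_kept += 1
    return kept, report


def kingdom_summary(
    hits: Sequence[SearchHit],
    query_kingdom: str,
    coverage_bins: Sequence[float] = (0.80, 0.30),
    pct_coverage_min: float | None = None,
    pct_coverage_max: float | None = None,
) -> pd.DataFrame:
    """Kingdom-diversity summary of a hit list.

    One row per coverage bin counts the hits at or above that coverage.
    The per-kingdom percentage columns are computed among hits *not* of
    the query's kingdom (optionally restricted to a coverage window via
    ``pct_coverage_min``/``pct_coverage_max``, exposed explicitly because
    summaries of this shape are reported over different windows);
    percentages over the five named kingdoms sum to at most 100%, with
    hits of unmapped kingdom counted in a separate column.
    """
    def in_window(h: SearchHit) -> bool:
        c = h.coverage
        if pct_coverage_min is not None and c < pct_coverage_min:
            return False
        if pct_coverage_max is not None and c >= pct_coverage_max:
            return False
        return True

    other = [h for h in hits if h.kingdom != query_kingdom and in_window(h)]
    denom = len(other)
    pct = {
        k: (100.0 * sum(1 for h in other if h.kingdom == k) / denom if denom else 0.0)
        for k in KINGDOMS
    }
    n_unknown = sum(1 for h in other if h.kingdom == "unknown")
    rows = []
    for b in coverage_bins:
        rows.append(
            {
                "coverage_bin": b,
                "n_hits": sum(1 for h in hits if h.coverage >= b),
                **{f"pct_{k}": pct[k] for k in KINGDOMS},
                "n_unknown_kingdom": n_unknown,
            }
        )
    return pd.DataFrame(rows)


def format_kingdom_summary(summary: pd.DataFrame) -> str:
    """Render the summary with zero percentages shown as "None"."""
    out = summary.copy()
    for col in out.columns:
        if col.startswith("pct_"):
            out[col] = out[col].map(lambda v: "None" if v == 0 else f"{v:.1f}%")
    return out.to_string(index=False)


@dataclass(frozen=True)
class ProfileResult:
    """Scatter table, rank correlation and identity-band segments."""

    table: pd.DataFrame
    spearman_rho: float | None   # None: too few pairs; NaN: zero variance
    segments: tuple[tuple[float, float, int], ...]


def rmsd_identity_profile(
    pairs: Sequence[tuple[float, float]],
    band_width: float = 0.05,
    density_factor: float = 2.0,
) -> ProfileResult:
    """Rmsd-versus-identity scatter with Spearman rho and step detection.

    A clear inverse rank correlation is the expected signature when
    predicted-structure quality tracks sequence identity.  The step
    detector reports contiguous identity bands (default width 5
    percentage points) whose occupancy exceeds ``density_factor`` times
    the uniform expectation — the banded "staircase" appearance of some
    query families.  Fewer than 3 pairs: correlation undefined (None);
    zero variance in either variable: NaN, flagged to the caller.
    """
    table = pd.DataFrame(pairs, columns=["rmsd", "identity"])
    if len(pairs) < 3:
        return ProfileResult(table=table, spearman_rho=None, segments=())
    rmsd = table["rmsd"].to_numpy()
    ident = table["identity"].to_numpy()
    if np.ptp(rmsd) == 0 or np.ptp(ident) == 0:
        rho: float | None = float("nan")
    else:
        rho = float(stats.spearmanr(rmsd, ident).statistic)
    n_bins = max(1, int(np.ceil(1.0 / band_width)))
    counts, edges = np.histogram(ident, bins=n_bins, range=(0.0, 1.0))
    threshold = density_factor * len(pairs) / n_bins
    dense = counts > threshold
    segments: list[tuple[float, float, int]] = []
    i = 0
    while i < n_bins:
        if dense[i]:
            j = i
            while j + 1 < n_bins and dense[j + 1]:
                j += 1
            segments.append((float(edges[i]), float(edges[j + 1]), int(counts[i:j + 1].sum())))
            i = j + 1
        else:
            i += 1
    return ProfileResult(table=table, spearman_rho=rho, segments=tuple(segments))


def select_representatives(
    hits: Sequence[SearchHit],
    architectures: Mapping[str, DomainArchitecture],
) -> tuple[list[str], list[str]]:
    """One hit id per distinct domain-architecture signature.

    Within a signature the hit with the lowest rmsd wins, ties broken by
    lexicographically smaller id.  Hits without an architecture entry are
    skipped and returned as errors.  Output order is by signature.
    """
    best: dict[tuple[str, ...], tuple[float, str]] = {}
    errors: list[str] = []
    for h in hits:
        arch = architectures.get(h.target_id)
        if arch is None:
            errors.append(f"{h.target_id}: no architecture annotation")
            continue
        sig = architecture_signature(arch)
        key = (h.rmsd, h.target_id)
        if sig not in best or key < best[sig]:
            best[sig] = key
    ids = [best[sig][1] for sig in sorted(best)]
    return ids, errors
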