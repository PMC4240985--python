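"""Per-locus informativeness statistics and marker screening.

Implements the quantities used to screen sequence markers for resolving
power before phylogenetic and parentage analysis:

* variable-site and parsimony-informative-site counts (and percentages),
* nucleotide diversity per site (pi), the average pairwise proportion of
  differing sites,
* a chi-square test for heterogeneity of base composition among taxa,
* a MaxChi-style sliding-window chi-square scan for intragenic
  recombination breakpoints,
* ranking and top-k selection of the most informative markers per genome.

Gap/N policy: gaps and ``N`` are missing data.  They are excluded pairwise
for pi and per column for site counts.  ``strict_gaps=True`` treats ``-``
as a fifth character state instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .alignment import Alignment

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class MarkerStats:
    """Summary statistics for one locus."""

    locus: str
    genome: str
    aligned_length: int
    variable_pct: float
    pi_informative_pct: float
    pi_diversity: float
    chi2_stat: float
    chi2_df: int
    chi2_p: float
    recombination_flag: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi_informative_pct <= self.variable_pct <= 100.0):
            raise ValueError(
                "require 0 <= PI% <= variable% <= 100, got "
                f"PI={self.pi_informative_pct}, var={self.variable_pct}"
            )
        if self.pi_diversity < 0:
            raise ValueError("pi must be non-negative")


def _state_counts(aln: Alignment, strict_gaps: bool) -> np.ndarray:
    """Per-column counts of each countable state, shape (n_states, length)."""
    states = np.append(_BASES, ord("-")) if strict_gaps else _BASES
    return np.array([(aln.matrix == s).sum(axis=0) for s in states])


def variable_site_count(aln: Alignment, strict_gaps: bool = False) -> int:
    """Number of columns with >= 2 distinct non-missing states."""
    if aln.n_rows == 0 or aln.length == 0:
        raise ValueError("empty alignment")
    counts = _state_counts(aln, strict_gaps)
    return int(((counts > 0).sum(axis=0) >= 2).sum())


def parsimony_informative_count(aln: Alignment, strict_gaps: bool = False) -> int:
    """Number of columns with >= 2 states each carried by >= 2 rows."""
    if aln.n_rows == 0 or aln.length == 0:
        raise ValueError("empty alignment")
    counts = _state_counts(aln, strict_gaps)
    return int(((counts >= 2).sum(axis=0) >= 2).sum())


def nucleotide_diversity(aln: Alignment, strict_gaps: bool = False) -> float:
    """Nucleotide diversity per site (pi).

    Average over all unordered row pairs of (pairwise differences /
    pairwise compared sites); sites where either row is missing are
    excluded for that pair.  Pairs with no comparable site are skipped;
    if no pair is comparable a :class:`ValueError` is raised.
    """
    if aln.n_rows < 2:
        raise ValueError("pi requires >= 2 rows")
    missing = aln.missing_mask()
    if strict_gaps:
        missing = aln.matrix == ord("N")
    vals = []
    for i, j in combinations(range(aln.n_rows), 2):
        ok = ~(missing[i] | missing[j])
        n = int(ok.sum())
        if n == 0:
            continue
        diffs = int((aln.matrix[i, ok] != aln.matrix[j, ok]).sum())
        vals.append(diffs / n)
    if not vals:
        raise ValueError("no pair of rows shares a comparable site")
    return float(np.mean(vals))


def base_composition_chi2(aln: Alignment) -> tuple[float, int, float]:
    """Chi-square test of base-composition homogeneity among taxa.

    Builds the taxa x {A,C,G,T} count table (missing excluded), drops
    bases absent from every row (df adjusted accordingly) and rows with no
    countable base (with a warning), and returns ``(statistic, df, p)``
    from the uncorrected chi-square upper tail.
    """
    if aln.n_rows < 2:
        raise ValueError("chi2 requires >= 2 rows")
    table = np.array([(aln.matrix == b).sum(axis=1) for b in _BASES]).T
    row_ok = table.sum(axis=1) > 0
    if not row_ok.all():
        skipped = [aln.labels[i] for i in np.flatnonzero(~row_ok)]
        warnings.warn(f"rows with no countable bases excluded: {skipped}")
        table = table[row_ok]
    if table.shape[0] < 2:
        raise ValueError("fewer than 2 rows with countable bases")
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        # every surviving row is a single repeated base: perfectly homogeneous
        return 0.0, 0, 1.0
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def maxchi_scan(
    aln: Alignment,
    window: int = 400,
    alpha: float = 0.05,
) -> list[tuple[tuple[str, str], int, float]]:
    """MaxChi-style recombination scan over all sequence pairs.

    For each pair, mismatch indicators at mutually non-missing sites are
    compared left versus right of a sliding breakpoint in a window of
    ``window`` comparable sites (``window // 2`` each side) with an
    uncorrected 2x2 chi-square.  The per-pair maximum is Bonferroni
    corrected over pairs x breakpoints within the locus; candidates with
    corrected p < ``alpha`` are returned as
    ``((label_i, label_j), breakpoint_column, corrected_p)`` sorted by p.
    """
    if aln.n_rows < 3:
        raise ValueError("maxchi scan requires >= 3 rows")
    if not (4 <= window < aln.length):
        raise ValueError(
            f"window must satisfy 4 <= window < aligned length ({aln.length})"
        )
    half = window // 2
    missing = aln.missing_mask()
    candidates: list[tuple[tuple[str, str], int, float]] = []
    n_tests = 0
    for i, j in combinations(range(aln.n_rows), 2):
        ok = np.flatnonzero(~(missing[i] | missing[j]))
        if ok.size < window + 1:
            continue
        mm = (aln.matrix[i, ok] != aln.matrix[j, ok]).astype(np.int64)
        if mm.sum() == 0:
            continue
        c = np.concatenate([[0], np.cumsum(mm)])
        # breakpoint index b in comparable coordinates: half <= b <= len-half
        b = np.arange(half, ok.size - half + 1)
        left = c[b] - c[b - half]
        right = c[b + half] - c[b]
        n_tests += b.size
        a11, a12 = left, half - left
        a21, a22 = right, half - right
        rs1, rs2 = a11 + a12, a21 + a22
        cs1, cs2 = a11 + a21, a12 + a22
        denom = rs1 * rs2 * cs1 * cs2
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.where(
                denom > 0,
                (rs1 + rs2) * (a11 * a22 - a12 * a21) ** 2 / denom,
                0.0,
            )
        k = int(np.argmax(chi2))
        best = float(chi2[k])
        if best <= 0:
            continue
        p = float(stats.chi2.sf(best, df=1))
        candidates.append(
            ((aln.labels[i], aln.labels[j]), int(ok[b[k] - 1]) + 1, p)
        )
    out = []
    for pair, pos, p in candidates:
        p_adj = min(1.0, p * n_tests)
        if p_adj < alpha:
            out.append((pair, pos, p_adj))
    out.sort(key=lambda t: (t[2], t[1]))
    return out


def compute_marker_stats(
    aln: Alignment, run_maxchi: bool = False, window: int = 400
) -> MarkerStats:
    """Compute the full statistics row for one locus."""
    length = aln.length
    var = variable_site_count(aln)
    pi_sites = parsimony_informative_count(aln)
    stat, df, p = base_composition_chi2(aln)
    flag = False
    if run_maxchi and aln.n_rows >= 3 and window < length:
        flag = bool(maxchi_scan(aln, window=window))
    return MarkerStats(
        locus=aln.locus,
        genome=aln.genome,
        aligned_length=length,
        variable_pct=100.0 * var / length,
        pi_informative_pct=100.0 * pi_sites / length,
        pi_diversity=nucleotide_diversity(aln),
        chi2_stat=stat,
        chi2_df=df,
        chi2_p=p,
        recombination_flag=flag,
    )


def rank_and_select_markers(
    all_stats: list[MarkerStats], k: int, genome: str
) -> list[str]:
    """Top ``k`` locus ids of the given genome by informativeness.

    Sort key: parsimony-informative % (desc), then variable % (desc), then
    aligned length (desc), then locus id (asc) — an explicit convention for
    "most informative".  Input order never affects the selection.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    pool = [s for s in all_stats if s.genome == genome]
    if k > len(pool):
        raise ValueError(f"k={k} exceeds {len(pool)} loci tagged {genome!r}")
    pool.sort(
        key=lambda s: (
            -s.pi_informative_pct,
            -s.variable_pct,
            -s.aligned_length,
            s.locus,
        )
    )
    return [s.locus for s in pool[:k]]


def stats_table(all_stats: list[MarkerStats]) -> "pd.DataFrame":  # noqa: F821
    """Tabulate marker statistics (percentages to 1 decimal)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "locus": [s.locus for s in all_stats],
            "genome": [s.genome for s in all_stats],
            "aligned_length": [s.aligned_length for s in all_stats],
            "variable_pct": [round(s.variable_pct, 1) for s in all_stats],
            "pi_informative_pct": [
                round(s.pi_informative_pct, 1) for s in all_stats
            ],
            "pi_diversity": [round(s.pi_diversity, 5) for s in all_stats],
            "chi2_stat": [round(s.chi2_stat, 3) for s in all_stats],
            "chi2_df": [s.chi2_df for s in all_stats],
            "chi2_p": [round(s.chi2_p, 4) for s in all_stats],
            "recombination_flag": [s.recombination_flag for s in all_stats],
        }
    )
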