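"""Multilocus identity-based parentage inference for hybrid cultivars.

The inference chain mirrors how hybrid origins are read off cloned Sanger
data: cloned sequences per cultivar and locus are dereplicated into allele
haplotypes (filtering likely PCR/sequencing artifacts), each haplotype is
matched against the wild-species reference panel by strict sequence
identity (a tolerance mode exists), the maternal donor is assigned from
the chloroplast haplotype by minimum p-distance, and the parental species
set of each cultivar is the minimum-cardinality set of species that
explains every matched marker (a set cover constrained to contain the
maternal donor).  Unmatched alleles never invent parents — they are
reported as unexplained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

#: default ceiling for maternal assignment: 2 mismatches per kb
DEFAULT_CP_DISTANCE_CEILING = 0.002

_MISSING = frozenset(b"N-")


def _to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _mismatch(a: np.ndarray, b: np.ndarray) -> tuple[int, int]:
    """(mismatches, compared sites) with N/- excluded pairwise."""
    miss_a = (a == ord("N")) | (a == ord("-"))
    miss_b = (b == ord("N")) | (b == ord("-"))
    ok = ~(miss_a | miss_b)
    return int((a[ok] != b[ok]).sum()), int(ok.sum())


# ---------------------------------------------------------------------------
# reference panel and observations
# ---------------------------------------------------------------------------


@dataclass
class SpeciesReference:
    """Wild-species allele sets per locus plus chloroplast haplotypes."""

    nuclear: dict  # locus -> species -> tuple of allele strings
    cp: dict  # species -> haplotype string

    def __post_init__(self) -> None:
        for locus, by_sp in self.nuclear.items():
            for sp, alleles in by_sp.items():
                if not alleles:
                    raise ValueError(
                        f"species {sp!r} has no allele at locus {locus!r}"
                    )

    @property
    def species(self) -> set:
        out = set(self.cp)
        for by_sp in self.nuclear.values():
            out.update(by_sp)
        return out

    def locus_length(self, locus: str) -> int:
        by_sp = self.nuclear[locus]
        return len(next(iter(next(iter(by_sp.values())))))


def reference_from_panel(panel) -> SpeciesReference:
    """Build a :class:`SpeciesReference` from a simulated species panel."""
    nuclear: dict = {}
    for locus, aln in panel.loci.items():
        by_sp: dict = {}
        for lbl, seq in zip(aln.labels, aln.sequences()):
            sp = lbl.split("|")[1]
            by_sp.setdefault(sp, [])
            if seq not in by_sp[sp]:
                by_sp[sp].append(seq)
        nuclear[locus] = {sp: tuple(v) for sp, v in by_sp.items()}
    return SpeciesReference(nuclear, dict(panel.cp_haplotypes))


@dataclass
class AlleleObservation:
    """Dereplicated allele haplotypes of one cultivar at one locus."""

    cultivar: str
    locus: str
    alleles: list  # (haplotype string, clone count), count-descending

    def __post_init__(self) -> None:
        haps = [h for h, _ in self.alleles]
        if len(set(haps)) != len(haps):
            raise ValueError("duplicate haplotypes in one observation")
        if any(c < 1 for _, c in self.alleles):
            raise ValueError("clone counts must be >= 1")


def dereplicate_clones(
    clones: list,
    min_count: int = 2,
    refs: SpeciesReference | None = None,
    locus: str | None = None,
    cultivar: str = "",
) -> AlleleObservation:
    """Collapse identical clones into haplotypes with counts.

    Haplotypes seen fewer than ``min_count`` times are treated as likely
    PCR/sequencing artifacts and discarded — unless they exactly match a
    reference allele (the rescue rule).  The most frequent haplotype is
    always retained so an observation is never emptied.
    """
    if not clones:
        raise ValueError("empty clone list")
    counts: dict[str, int] = {}
    for c in clones:
        c = c.upper()
        counts[c] = counts.get(c, 0) + 1
    ref_alleles: set = set()
    if refs is not None and locus is not None and locus in refs.nuclear:
        for alleles in refs.nuclear[locus].values():
            ref_alleles.update(alleles)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    kept = [
        (h, n)
        for h, n in ranked
        if n >= min_count or h in ref_alleles
    ]
    if not kept:
        kept = [ranked[0]]
    return AlleleObservation(cultivar, locus or "", kept)


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------


def match_allele(
    haplotype: str,
    refs: SpeciesReference,
    locus: str,
    max_mismatch: int = 0,
) -> set:
    """Species whose reference alleles the haplotype matches.

    Default is strict 100% identity over pairwise non-missing sites; with
    ``max_mismatch > 0`` the nearest species within tolerance are returned
    (all species at the minimal mismatch count)."""
    if locus not in refs.nuclear:
        raise KeyError(f"locus {locus!r} not in reference")
    length = refs.locus_length(locus)
    if len(haplotype) != length:
        raise ValueError(
            f"haplotype length {len(haplotype)} != reference alignment "
            f"length {length} for locus {locus!r}"
        )
    hap = _to_arr(haplotype)
    best: dict[str, int] = {}
    for sp, alleles in refs.nuclear[locus].items():
        for allele in alleles:
            mm, _ = _mismatch(hap, _to_arr(allele))
            if sp not in best or mm < best[sp]:
                best[sp] = mm
    if max_mismatch == 0:
        return {sp for sp, mm in best.items() if mm == 0}
    within = {sp: mm for sp, mm in best.items() if mm <= max_mismatch}
    if not within:
        return set()
    lo = min(within.values())
    return {sp for sp, mm in within.items() if mm == lo}


@dataclass
class ParentageMatrix:
    """Cultivar x marker grid of matched species sets (machine-readable
    allele-sharing figure); unmatched haplotypes tallied per cell.

    ``cells`` holds the per-marker union used for display; ``allele_cells``
    keeps one match set per retained haplotype, which is what parental-set
    inference must explain (a diploid marker carries two alleles that may
    demand two different parents)."""

    cultivars: list
    markers: list  # nuclear locus ids, in analysis order
    cells: dict  # (cultivar, marker) -> frozenset of species
    unmatched: dict  # (cultivar, marker) -> count of unmatched haplotypes
    allele_cells: dict = None  # (cultivar, marker) -> tuple of frozensets

    def __post_init__(self) -> None:
        if self.allele_cells is None:
            self.allele_cells = {
                key: (cell,) if cell else ()
                for key, cell in self.cells.items()
            }

    def row(self, cultivar: str) -> dict:
        return {m: self.cells.get((cultivar, m), frozenset()) for m in self.markers}

    def allele_constraints(self, cultivar: str) -> list:
        out = []
        for m in self.markers:
            out.extend(self.allele_cells.get((cultivar, m), ()))
        return out


def build_parentage_matrix(
    observations: list, refs: SpeciesReference, max_mismatch: int = 0
) -> ParentageMatrix:
    """Union of allele matches per cultivar per marker."""
    for obs in observations:
        if obs.locus not in refs.nuclear:
            raise KeyError(f"locus {obs.locus!r} not in reference")
    cultivars: list = []
    markers: list = []
    cells: dict = {}
    unmatched: dict = {}
    allele_cells: dict = {}
    for obs in observations:
        if obs.cultivar not in cultivars:
            cultivars.append(obs.cultivar)
        if obs.locus not in markers:
            markers.append(obs.locus)
        key = (obs.cultivar, obs.locus)
        matched: set = set(cells.get(key, frozenset()))
        per_allele = list(allele_cells.get(key, ()))
        miss = unmatched.get(key, 0)
        for hap, _count in obs.alleles:
            hits = match_allele(hap, refs, obs.locus, max_mismatch)
            if hits:
                matched |= hits
                per_allele.append(frozenset(hits))
            else:
                miss += 1
        cells[key] = frozenset(matched)
        allele_cells[key] = tuple(per_allele)
        unmatched[key] = miss
    return ParentageMatrix(cultivars, markers, cells, unmatched, allele_cells)


# ---------------------------------------------------------------------------
# maternal assignment
# ---------------------------------------------------------------------------


@dataclass
class MaternalAssignment:
    species: str | None
    distance: float
    ties: tuple = ()
    exact: bool = False


def assign_maternal(
    cp_haplotype: str,
    refs: SpeciesReference,
    distance_ceiling: float = DEFAULT_CP_DISTANCE_CEILING,
    nuclear_matches: dict | None = None,
) -> MaternalAssignment:
    """Maternal donor = species with the minimum chloroplast p-distance.

    Distance zero is reported as exact.  Ties at the minimum are recorded;
    the primary is the tied species matching at the most nuclear markers
    (``nuclear_matches``: species -> count), then the lexically first.
    A minimum above ``distance_ceiling`` leaves the cultivar unassigned.
    """
    if not refs.cp:
        raise ValueError("empty chloroplast reference")
    hap = _to_arr(cp_haplotype)
    dist: dict[str, float] = {}
    for sp, ref_hap in refs.cp.items():
        mm, n = _mismatch(hap, _to_arr(ref_hap))
        if n == 0:
            continue
        dist[sp] = mm / n
    if not dist:
        return MaternalAssignment(None, float("nan"))
    lo = min(dist.values())
    tied = sorted(sp for sp, d in dist.items() if d == lo)
    if lo > distance_ceiling:
        return MaternalAssignment(None, lo, tuple(tied))
    nm = nuclear_matches or {}
    primary = min(tied, key=lambda sp: (-nm.get(sp, 0), sp))
    return MaternalAssignment(
        primary, lo, tuple(tied) if len(tied) > 1 else (), exact=(lo == 0.0)
    )


# ---------------------------------------------------------------------------
# parental-set inference (set cover)
# ---------------------------------------------------------------------------


def _coverage(cover: frozenset, cells: list) -> int:
    return sum(len(cover & cell) for cell in cells)


def infer_parent_set(
    row: dict,
    maternal: str | None = None,
    known_species: set | None = None,
    exact_max_candidates: int = 15,
) -> tuple[frozenset, list]:
    """Minimum species set explaining every matched allele of a cultivar.

    ``row`` is either a mapping marker -> set of matched species (one
    constraint per marker) or an iterable of match sets (one constraint
    per allele, the diploid-aware form used by the pipeline); empty cells
    constrain nothing.  The cover must contain the maternal species when assigned
    (unless the maternal species appears in no cell and is unknown to the
    reference, which is flagged as an inconsistency and ignored).  Exact
    subset search up to ``exact_max_candidates`` candidate species, greedy
    beyond.  Returns ``(primary, co_optimal)``; co-optimal covers are
    ordered by total marker coverage (descending) then lexically.
    """
    raw = row.values() if hasattr(row, "values") else row
    cells = [frozenset(c) for c in raw if c]
    forced: set = set()
    if maternal is not None:
        in_cells = any(maternal in c for c in cells)
        known = known_species is not None and maternal in known_species
        if not in_cells and known_species is not None and not known:
            warnings.warn(
                f"maternal species {maternal!r} absent from all markers and "
                "from the reference; computing cover without the constraint"
            )
        else:
            forced = {maternal}
    candidates = sorted(set().union(*cells) | forced) if (cells or forced) else []
    if not candidates:
        raise ValueError("no matched marker and no maternal constraint")

    free = [c for c in candidates if c not in forced]
    uncovered = [c for c in cells if not (c & forced)]

    if len(candidates) <= exact_max_candidates:
        solutions: list[frozenset] = []
        for extra in range(len(free) + 1):
            for combo in combinations(free, extra):
                cover = frozenset(forced | set(combo))
                if all(c & cover for c in uncovered):
                    solutions.append(cover)
            if solutions:
                break
        solutions.sort(key=lambda s: (-_coverage(s, cells), tuple(sorted(s))))
        return solutions[0], solutions
    # greedy fallback for large candidate sets
    cover = set(forced)
    remaining = [c for c in uncovered]
    while remaining:
        best_sp = max(
            free,
            key=lambda sp: (sum(1 for c in remaining if sp in c), sp),
        )
        cover.add(best_sp)
        remaining = [c for c in remaining if best_sp not in c]
    return frozenset(cover), [frozenset(cover)]


# ---------------------------------------------------------------------------
# calls and cohort summary
# ---------------------------------------------------------------------------


@dataclass
class ParentageCall:
    cultivar: str
    maternal: MaternalAssignment
    parental_set: frozenset
    co_optimal: list
    evidence: dict  # marker -> frozenset of matched species
    unexplained: dict  # marker -> count of unmatched haplotypes

    def __post_init__(self) -> None:
        if (
            self.maternal.species is not None
            and self.maternal.species not in self.parental_set
        ):
            raise ValueError("maternal species missing from parental set")


def call_parentage(
    matrix: ParentageMatrix,
    refs: SpeciesReference,
    cp_haplotypes: dict | None = None,
    distance_ceiling: float = DEFAULT_CP_DISTANCE_CEILING,
) -> list:
    """Per-cultivar maternal assignment + minimal parental set."""
    calls = []
    known = refs.species
    for cv in matrix.cultivars:
        row = matrix.row(cv)
        nuclear_matches = {
            sp: sum(1 for cell in row.values() if sp in cell)
            for sp in set().union(*row.values(), set())
        }
        maternal = MaternalAssignment(None, float("nan"))
        if cp_haplotypes and cv in cp_haplotypes:
            maternal = assign_maternal(
                cp_haplotypes[cv], refs, distance_ceiling, nuclear_matches
            )
        primary, co = infer_parent_set(
            matrix.allele_constraints(cv), maternal.species, known
        )
        calls.append(
            ParentageCall(
                cv,
                maternal,
                primary,
                co,
                row,
                {m: matrix.unmatched.get((cv, m), 0) for m in matrix.markers},
            )
        )
    return calls


@dataclass
class CohortSummary:
    parental_union: frozenset
    per_species_cultivar_counts: dict  # species -> n cultivars supported
    per_marker_species_freq: dict  # marker -> species -> n cultivars matched
    maternal_tally: dict  # species -> n cultivars assigned
    n_unassigned_maternal: int = 0


def cohort_summary(calls: list) -> CohortSummary:
    """Cohort-level aggregation of parentage calls."""
    if not calls:
        raise ValueError("no calls to summarize")
    union: set = set()
    sp_counts: dict = {}
    marker_freq: dict = {}
    maternal_tally: dict = {}
    unassigned = 0
    for call in calls:
        union |= call.parental_set
        for sp in call.parental_set:
            sp_counts[sp] = sp_counts.get(sp, 0) + 1
        for marker, cell in call.evidence.items():
            mf = marker_freq.setdefault(marker, {})
            for sp in cell:
                mf[sp] = mf.get(sp, 0) + 1
        if call.maternal.species is None:
            unassigned += 1
        else:
            maternal_tally[call.maternal.species] = (
                maternal_tally.get(call.maternal.species, 0) + 1
            )
    return CohortSummary(
        frozenset(union), sp_counts, marker_freq, maternal_tally, unassigned
    )
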