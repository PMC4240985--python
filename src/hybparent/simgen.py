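"""Synthetic homoploid-hybridization datasets with known truth.

The generator emulates the structure of a multilocus Sanger-style study of
hybrid-origin cultivars: a panel of wild species (two clades from a Yule
species tree) carrying one to a few sequenced accessions per nuclear locus
and a single linked chloroplast haplotype each, plus a cohort of cultivars.
Each cultivar is a first-generation homoploid hybrid by default: it inherits
its chloroplast from a maternal species and, at every nuclear locus, one
allele from each of its two parents; alleles are observed through cloned
sequences with optional per-site error.  Inter-species chloroplast capture
can be injected among the wild taxa to create cyto-nuclear discordance.

Every random draw is fixed by the configured seed; identical configurations
produce byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import dendropy
import numpy as np

from .alignment import Alignment, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {b: i for i, b in enumerate(b"ACGT")}


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    Defaults describe the emulated study design: 9 wild species in two
    clades, 25 nuclear loci of 322-3656 bp whose substitution scales span
    roughly 4-19% variable sites, one ~3 kb linked chloroplast haplotype of
    lower diversity, and 47 cultivars bred from a 5-species parental pool
    with one dominant maternal donor.  Post-origin mutation and clone error
    default to zero so that every cultivar allele is an exact copy of a
    panel allele (the identity-matching regime); both are per-site rates
    that can be raised to study degradation.
    """

    n_species: int = 9
    birth_rate: float = 1.0
    n_nuclear_loci: int = 25
    locus_length_range: tuple[int, int] = (322, 3656)
    nuclear_rate_range: tuple[float, float] = (0.005, 0.025)
    model: str = "JC69"
    kappa: float = 2.0
    cp_length: int = 3000
    cp_rate: float = 0.008
    accessions_per_species: tuple[int, int] = (2, 3)
    within_species_rate: float = 0.0015
    n_cultivars: int = 47
    parental_pool_size: int = 5
    parental_set_sizes: tuple[tuple[int, float], ...] = ((2, 1.0),)
    dominant_maternal_weight: float = 0.7
    post_origin_mutation_rate: float = 0.0
    n_clones_range: tuple[int, int] = (8, 16)
    clone_error_rate: float = 0.0
    capture_probability: float = 0.0
    ensure_species_private_alleles: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")
        for name in (
            "cp_rate",
            "within_species_rate",
            "post_origin_mutation_rate",
            "clone_error_rate",
            "capture_probability",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.locus_length_range[0] < 1 or self.cp_length < 1:
            raise ValueError("locus lengths must be >= 1")
        if self.parental_pool_size > self.n_species:
            raise ValueError("parental pool larger than the species panel")
        if any(k > self.parental_pool_size for k, _ in self.parental_set_sizes):
            raise ValueError("parental-set size exceeds the pool")


@dataclass
class CultivarTruth:
    maternal_species: str
    parental_set: frozenset
    per_locus_allele_origins: dict

    def __post_init__(self) -> None:
        if self.maternal_species not in self.parental_set:
            raise ValueError("maternal species must be in the parental set")
        if len(self.parental_set) < 1:
            raise ValueError("parental set must be non-empty")
        for origins in self.per_locus_allele_origins.values():
            if any(o not in self.parental_set for o in origins):
                raise ValueError("allele origin outside the parental set")


@dataclass
class SimTruth:
    """Per-cultivar true parentage plus wild chloroplast-capture events."""

    cultivars: dict  # cultivar id -> CultivarTruth
    capture_events: list = field(default_factory=list)


@dataclass
class Cultivar:
    """One simulated cultivar: chloroplast haplotype, true allele pairs per
    nuclear locus, and the cloned sequences actually 'observed'."""

    id: str
    cp_haplotype: str
    alleles: dict  # locus -> ((seq, origin_species), (seq, origin_species))
    clones: dict  # locus -> list of clone strings


@dataclass
class SpeciesPanel:
    """Wild reference panel: per-locus accession alignments, one linked
    chloroplast haplotype per species, and clade membership."""

    species_ids: list
    subsection_of: dict
    loci: dict  # locus id -> Alignment with rows "SPECIES|<sp>|<acc>"
    cp_haplotypes: dict  # species -> str
    species_tree: dendropy.Tree | None = None
    capture_events: list = field(default_factory=list)

    def validate(self) -> None:
        for locus, aln in self.loci.items():
            present = {lbl.split("|")[1] for lbl in aln.labels}
            missing = set(self.species_ids) - present
            if missing:
                raise ValueError(
                    f"species missing from locus {locus}: {sorted(missing)}"
                )
        missing_cp = set(self.species_ids) - set(self.cp_haplotypes)
        if missing_cp:
            raise ValueError(f"species without cp haplotype: {sorted(missing_cp)}")

    def copy(self) -> "SpeciesPanel":
        return SpeciesPanel(
            list(self.species_ids),
            dict(self.subsection_of),
            dict(self.loci),
            dict(self.cp_haplotypes),
            self.species_tree,
            list(self.capture_events),
        )


# ---------------------------------------------------------------------------
# species tree and sequence evolution
# ---------------------------------------------------------------------------


def simulate_species_tree(
    n_species: int, birth_rate: float = 1.0, seed: int = 0
) -> dendropy.Tree:
    """Rooted ultrametric pure-birth (Yule) species tree.

    The root splits at time zero; waiting times between successive
    speciations with ``k`` extant lineages are Exp(k * birth_rate); after
    the last split the tree grows for a final Exp(n * birth_rate) interval
    so every tip sits at the same depth.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    labels = [f"sp{i + 1:02d}" for i in range(n_species)]
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    root = dendropy.Node()
    a, b = dendropy.Node(), dendropy.Node()
    root.add_child(a)
    root.add_child(b)
    active = [(a, 0.0), (b, 0.0)]
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = int(rng.integers(k))
        node, born = active.pop(idx)
        node.edge.length = t - born
        c1, c2 = dendropy.Node(), dendropy.Node()
        node.add_child(c1)
        node.add_child(c2)
        active.extend([(c1, t), (c2, t)])
    t += rng.exponential(1.0 / (n_species * birth_rate))
    for (node, born), lbl in zip(active, labels):
        node.edge.length = t - born
        node.taxon = tns.get_taxon(lbl)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def _transition_matrix(
    model: str, rate: float, t: float, kappa: float = 2.0
) -> np.ndarray:
    """4x4 substitution probabilities over a branch of length ``t`` with
    ``rate`` expected substitutions per site per unit time (bases ACGT)."""
    d = rate * t
    if model == "JC69":
        same = 0.25 + 0.75 * np.exp(-4.0 * d / 3.0)
        diff = (1.0 - same) / 3.0
        P = np.full((4, 4), diff)
        np.fill_diagonal(P, same)
        return P
    if model == "K2P":
        beta = 1.0 / (kappa + 2.0)
        alpha = kappa * beta
        e1 = np.exp(-4.0 * beta * d)
        e2 = np.exp(-2.0 * (alpha + beta) * d)
        same = 0.25 + 0.25 * e1 + 0.5 * e2
        ts = 0.25 + 0.25 * e1 - 0.5 * e2
        tv = 0.25 - 0.25 * e1
        P = np.full((4, 4), tv)
        np.fill_diagonal(P, same)
        for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):  # A<->G, C<->T
            P[i, j] = ts
        return P
    raise ValueError(f"unknown substitution model {model!r}")


def _draw_children(
    parent_states: np.ndarray, P: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    cum = P.cumsum(axis=1)
    u = rng.random(parent_states.size)
    return (u[:, None] > cum[parent_states]).sum(axis=1).astype(np.int8)


def evolve_locus(
    tree: dendropy.Tree,
    length: int,
    rate: float,
    model: str = "JC69",
    seed: int = 0,
    kappa: float = 2.0,
) -> Alignment:
    """Evolve a gap-free locus of ``length`` sites down ``tree``.

    The root sequence is uniform over ACGT; each branch applies the
    closed-form JC69 or K2P transition matrix for its length.  One row per
    leaf, labelled with the leaf taxa.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    _transition_matrix(model, rate, 1.0, kappa)  # validate model name early
    rng = np.random.default_rng(seed)
    states = {
        tree.seed_node: rng.integers(0, 4, length).astype(np.int8)
    }
    labels, rows = [], []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        P = _transition_matrix(model, rate, t, kappa)
        states[node] = _draw_children(states[node.parent_node], P, rng)
        if node.is_leaf():
            labels.append(node.taxon.label)
            rows.append(_BASES[states[node]].tobytes().decode("ascii"))
    return Alignment.from_seqs(labels, rows)


def mutate_sequence(
    seq: str, rate: float, rng: np.random.Generator
) -> str:
    """Per-site substitution with probability ``rate``; a hit replaces the
    base with one of the three other bases uniformly.  Missing states are
    left untouched."""
    if rate == 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    is_base = np.isin(arr, _BASES)
    hits = np.flatnonzero((rng.random(arr.size) < rate) & is_base)
    if hits.size:
        shift = rng.integers(1, 4, hits.size)
        idx = np.array([_BASE_INDEX[b] for b in arr[hits]])
        arr[hits] = _BASES[(idx + shift) % 4]
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# panel construction
# ---------------------------------------------------------------------------


def _subsections(tree: dendropy.Tree) -> dict:
    left, right = tree.seed_node.child_nodes()
    out = {}
    for lf in left.leaf_iter():
        out[lf.taxon.label] = "subsect_A"
    for lf in right.leaf_iter():
        out[lf.taxon.label] = "subsect_B"
    return out


def _species_alleles_distinct(panel: SpeciesPanel) -> bool:
    """True when no identical allele is shared between species at any
    nuclear locus and all species cp haplotypes are pairwise distinct."""
    if len(set(panel.cp_haplotypes.values())) < len(panel.species_ids):
        return False
    for aln in panel.loci.values():
        owners: dict[str, str] = {}
        for lbl, seq in zip(aln.labels, aln.sequences()):
            sp = lbl.split("|")[1]
            if owners.setdefault(seq, sp) != sp:
                return False
    return True


def build_species_panel(cfg: SimConfig, seed: int | None = None) -> SpeciesPanel:
    """Simulate the wild reference panel for ``cfg``.

    With ``ensure_species_private_alleles`` (the identity-matching study
    condition) the panel is redrawn, with a perturbed seed, until every
    species carries a fully private allele set and a private chloroplast
    haplotype; at the default divergences a redraw is almost never needed.
    """
    base_seed = cfg.seed if seed is None else seed
    for attempt in range(20):
        panel = _build_panel_once(cfg, (base_seed + 7919 * attempt) % 2**31)
        if not cfg.ensure_species_private_alleles or _species_alleles_distinct(
            panel
        ):
            panel.validate()
            return panel
    raise RuntimeError(
        "could not draw a panel with species-private alleles; "
        "raise the substitution rates or locus lengths"
    )


def _build_panel_once(cfg: SimConfig, seed: int) -> SpeciesPanel:
    rng = np.random.default_rng(seed)
    tree = simulate_species_tree(
        cfg.n_species, cfg.birth_rate, seed=int(rng.integers(2**31))
    )
    species = [lf.taxon.label for lf in tree.leaf_node_iter()]
    n_acc = {
        sp: int(rng.integers(cfg.accessions_per_species[0],
                             cfg.accessions_per_species[1] + 1))
        for sp in species
    }
    loci: dict[str, Alignment] = {}
    for i in range(cfg.n_nuclear_loci):
        locus = f"L{i + 1:02d}"
        length = int(
            rng.integers(cfg.locus_length_range[0], cfg.locus_length_range[1] + 1)
        )
        rate = float(rng.uniform(*cfg.nuclear_rate_range))
        base = evolve_locus(
            tree, length, rate, cfg.model,
            seed=int(rng.integers(2**31)), kappa=cfg.kappa,
        )
        labels, rows = [], []
        for sp in species:
            base_seq = base.row(sp)
            for a in range(n_acc[sp]):
                labels.append(f"SPECIES|{sp}|a{a + 1}")
                rows.append(mutate_sequence(base_seq, cfg.within_species_rate, rng))
        loci[locus] = Alignment.from_seqs(labels, rows, locus, "nuclear")
    cp = evolve_locus(
        tree, cfg.cp_length, cfg.cp_rate, cfg.model,
        seed=int(rng.integers(2**31)), kappa=cfg.kappa,
    )
    return SpeciesPanel(
        species_ids=species,
        subsection_of=_subsections(tree),
        loci=loci,
        cp_haplotypes={sp: cp.row(sp) for sp in species},
        species_tree=tree,
    )


def select_discordance_probe(panel: SpeciesPanel) -> tuple[str, str, set]:
    """Pick a donor/recipient pair whose chloroplast capture is detectable
    at the clade level.

    Returns ``(donor, recipient, clade)`` where ``clade`` is the largest
    true clade of the species tree with 2..n-2 members containing the
    recipient, and the donor lies outside it, so that after capture the
    clade stops being monophyletic on the chloroplast tree while remaining
    monophyletic on the nuclear tree.
    """
    tree = panel.species_tree
    if tree is None:
        raise ValueError("panel has no species tree to probe")
    n = len(panel.species_ids)
    best: set | None = None
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        leaves = {lf.taxon.label for lf in node.leaf_iter()}
        if 2 <= len(leaves) <= n - 2 and (best is None or len(leaves) > len(best)):
            best = leaves
    if best is None:
        raise ValueError("species tree has no non-trivial clade")
    donor = sorted(set(panel.species_ids) - best)[0]
    recipient = sorted(best)[0]
    return donor, recipient, best


def apply_chloroplast_capture(
    panel: SpeciesPanel, donor: str, recipient: str
) -> SpeciesPanel:
    """Replace ``recipient``'s chloroplast haplotype with a copy of
    ``donor``'s (nuclear loci untouched) and record the event."""
    if donor == recipient:
        raise ValueError("donor and recipient must differ")
    for sp in (donor, recipient):
        if sp not in panel.cp_haplotypes:
            raise KeyError(f"species {sp!r} not in panel")
    out = panel.copy()
    out.cp_haplotypes[recipient] = panel.cp_haplotypes[donor]
    out.capture_events.append((donor, recipient))
    return out


# ---------------------------------------------------------------------------
# cultivars
# ---------------------------------------------------------------------------


def sample_clones(
    allele_pair: tuple[str, str],
    n_clones: int,
    error_rate: float,
    seed: int = 0,
) -> list[str]:
    """Cloned reads of a diploid locus: each clone copies one of the two
    alleles uniformly at random with independent per-site errors."""
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if not (0 <= error_rate < 1):
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, 2, n_clones)
    return [mutate_sequence(allele_pair[p], error_rate, rng) for p in picks]


def generate_cultivars(
    panel: SpeciesPanel, cfg: SimConfig, seed: int | None = None
) -> tuple[list[Cultivar], SimTruth]:
    """Breed the cultivar cohort from the panel.

    A parental pool of ``cfg.parental_pool_size`` species is drawn once;
    its first member is the dominant maternal donor, chosen as the
    maternal parent with probability ``dominant_maternal_weight``.  Each
    cultivar draws a parental set (default: two species, an F1), copies
    its chloroplast from the maternal species and one nuclear allele per
    parent per locus (a random accession's allele), applies post-origin
    mutation, and samples cloned sequences.
    """
    if not panel.species_ids:
        raise ValueError("empty species panel")
    panel.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    pool = list(
        rng.choice(panel.species_ids, size=cfg.parental_pool_size, replace=False)
    )
    dominant = pool[0]
    sizes, weights = zip(*cfg.parental_set_sizes)
    weights = np.asarray(weights, dtype=float)
    weights /= weights.sum()

    cultivars: list[Cultivar] = []
    truths: dict[str, CultivarTruth] = {}
    for i in range(cfg.n_cultivars):
        cid = f"cv{i + 1:03d}"
        size = int(rng.choice(sizes, p=weights))
        if rng.random() < cfg.dominant_maternal_weight:
            maternal = dominant
        else:
            maternal = str(rng.choice(pool))
        others = list(
            rng.choice(
                [s for s in pool if s != maternal], size=size - 1, replace=False
            )
        )
        parents = [maternal] + others
        cp = mutate_sequence(
            panel.cp_haplotypes[maternal], cfg.post_origin_mutation_rate, rng
        )
        alleles: dict = {}
        origins: dict = {}
        clones: dict = {}
        for locus, aln in panel.loci.items():
            if size == 2:
                pair_origin = (maternal, others[0])
            else:
                pair_origin = tuple(rng.choice(parents, size=2, replace=True))
            pair = []
            for origin in pair_origin:
                acc_rows = [
                    k for k, lbl in enumerate(aln.labels)
                    if lbl.split("|")[1] == origin
                ]
                src = aln.sequence(int(rng.choice(acc_rows)))
                pair.append(
                    mutate_sequence(src, cfg.post_origin_mutation_rate, rng)
                )
            alleles[locus] = ((pair[0], pair_origin[0]), (pair[1], pair_origin[1]))
            origins[locus] = pair_origin
            n_clones = int(
                rng.integers(cfg.n_clones_range[0], cfg.n_clones_range[1] + 1)
            )
            clones[locus] = sample_clones(
                (pair[0], pair[1]),
                n_clones,
                cfg.clone_error_rate,
                seed=int(rng.integers(2**31)),
            )
        parental_set = frozenset({maternal} | set().union(*origins.values()))
        cultivars.append(Cultivar(cid, cp, alleles, clones))
        truths[cid] = CultivarTruth(maternal, parental_set, origins)
    return cultivars, SimTruth(truths, list(panel.capture_events))


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[SpeciesPanel, list[Cultivar], SimTruth]:
    """Panel + optional wild chloroplast captures + cultivar cohort."""
    panel = build_species_panel(cfg)
    rng = np.random.default_rng((cfg.seed + 104729) % 2**31)
    if cfg.capture_probability > 0:
        for sp in list(panel.species_ids):
            if rng.random() < cfg.capture_probability:
                donor = str(
                    rng.choice([s for s in panel.species_ids if s != sp])
                )
                panel = apply_chloroplast_capture(panel, donor, sp)
    cultivars, truth = generate_cultivars(
        panel, cfg, seed=(cfg.seed + 15485863) % 2**31
    )
    return panel, cultivars, truth


# ---------------------------------------------------------------------------
# dataset writer
# ---------------------------------------------------------------------------


def write_dataset(
    panel: SpeciesPanel,
    cultivars: list[Cultivar],
    truth: SimTruth,
    out_dir: str | Path,
    cfg: SimConfig | None = None,
) -> dict:
    """Write the dataset as aligned FASTA + TSV truth + config echo.

    Returns a manifest dict; ``manifest["fasta_files"]`` lists one file per
    nuclear locus plus the chloroplast file.  Labels follow the
    ``SPECIES|<species>|<accession>`` / ``CULTIVAR|<name>|clone<N>``
    convention; the cultivar chloroplast row is ``CULTIVAR|<name>``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta_files: list[str] = []
    for locus, aln in sorted(panel.loci.items()):
        pairs = list(zip(aln.labels, aln.sequences()))
        for cv in cultivars:
            for k, clone in enumerate(cv.clones[locus]):
                pairs.append((f"CULTIVAR|{cv.id}|clone{k + 1}", clone))
        path = out / f"locus_{locus}.fasta"
        write_fasta(pairs, path)
        fasta_files.append(path.name)
    cp_pairs = [
        (f"SPECIES|{sp}", panel.cp_haplotypes[sp]) for sp in panel.species_ids
    ]
    cp_pairs += [(f"CULTIVAR|{cv.id}", cv.cp_haplotype) for cv in cultivars]
    cp_path = out / "chloroplast.fasta"
    write_fasta(cp_pairs, cp_path)
    fasta_files.append(cp_path.name)

    truth_path = out / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("cultivar\tmaternal_species\tparental_set\n")
        for cid in sorted(truth.cultivars):
            ct = truth.cultivars[cid]
            fh.write(
                f"{cid}\t{ct.maternal_species}\t"
                + ";".join(sorted(ct.parental_set))
                + "\n"
            )
    origins_path = out / "origins.tsv"
    with open(origins_path, "w") as fh:
        fh.write("cultivar\tlocus\tallele_index\torigin_species\n")
        for cid in sorted(truth.cultivars):
            for locus in sorted(truth.cultivars[cid].per_locus_allele_origins):
                origins = truth.cultivars[cid].per_locus_allele_origins[locus]
                for k, origin in enumerate(origins):
                    fh.write(f"{cid}\t{locus}\t{k}\t{origin}\n")
    capture_path = out / "capture_events.tsv"
    with open(capture_path, "w") as fh:
        fh.write("donor\trecipient\n")
        for donor, recipient in truth.capture_events:
            fh.write(f"{donor}\t{recipient}\n")

    manifest = {
        "fasta_files": fasta_files,
        "truth": truth_path.name,
        "origins": origins_path.name,
        "capture_events": capture_path.name,
    }
    if cfg is not None:
        cfg_path = out / "config.toml"
        cfg_path.write_text(config_to_toml(cfg))
        manifest["config"] = cfg_path.name
    return manifest


def config_to_toml(cfg: SimConfig) -> str:
    """Plain key-value (TOML-style) echo of a configuration."""
    lines = ["[simulation]"]
    for f in fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, str):
            lines.append(f'{f.name} = "{v}"')
        elif isinstance(v, bool):
            lines.append(f"{f.name} = {str(v).lower()}")
        elif isinstance(v, tuple):
            lines.append(f"{f.name} = {list(map(list, v)) if v and isinstance(v[0], tuple) else list(v)}")
        else:
            lines.append(f"{f.name} = {v}")
    return "\n".join(lines) + "\n"


def config_from_dict(d: dict) -> SimConfig:
    """Build a :class:`SimConfig` from a parsed TOML/dict, coercing lists
    back to tuples."""
    kwargs = {}
    valid = {f.name for f in fields(SimConfig)}
    for k, v in d.items():
        if k not in valid:
            raise ValueError(f"unknown simulation config key {k!r}")
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kwargs[k] = v
    return SimConfig(**kwargs)


__all__ = [
    "SimConfig",
    "SimTruth",
    "CultivarTruth",
    "Cultivar",
    "SpeciesPanel",
    "simulate_species_tree",
    "evolve_locus",
    "mutate_sequence",
    "build_species_panel",
    "apply_chloroplast_capture",
    "sample_clones",
    "generate_cultivars",
    "simulate_dataset",
    "write_dataset",
    "config_to_toml",
    "config_from_dict",
]
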