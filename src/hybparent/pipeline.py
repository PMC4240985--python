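"""End-to-end orchestration: data in, parentage calls and reports out.

Stage order: load or simulate -> marker statistics and selection ->
nuclear and chloroplast trees with discordance -> parentage matrix ->
per-cultivar calls -> cohort summary -> (when simulation truth is
available) recovery report.  Every artifact is plain text (TSV, Newick,
FASTA, TOML-style config echo) and every stochastic stage is driven by
the configured seed, so a rerun with the same configuration is
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from . import markerstats as ms
from . import parentage as pg
from . import simgen
from . import treekit as tk
from .alignment import Alignment, read_alignment, read_fasta

logger = logging.getLogger("hybparent")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    simulation: simgen.SimConfig | None = None
    input_dir: str | None = None
    select_k_nuclear: int = 7
    builder: str = "nj"
    bootstrap_reps: int = 100
    max_mismatch: int = 0
    min_count: int = 2
    cp_distance_ceiling: float = pg.DEFAULT_CP_DISTANCE_CEILING
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.simulation is None and self.input_dir is None:
            raise ValueError("config needs either a simulation or an input_dir")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise ValueError(f"input_dir does not exist: {self.input_dir}")


def config_from_toml(path: str | Path, **overrides) -> PipelineConfig:
    """Load a TOML config; keyword overrides (e.g. from CLI flags) win."""
    import tomllib

    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    kwargs = dict(doc.get("pipeline", {}))
    if "simulation" in doc:
        kwargs["simulation"] = simgen.config_from_dict(doc["simulation"])
    if "input" in doc:
        kwargs["input_dir"] = doc["input"].get("dir")
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    cfg = PipelineConfig(**kwargs)
    if cfg.simulation is not None and "seed" not in doc.get("simulation", {}):
        cfg = replace(cfg, simulation=replace(cfg.simulation, seed=cfg.seed))
    return cfg


@dataclass
class RecoveryReport:
    """How well inference recovered the simulated truth."""

    cohort_precision: float | None
    cohort_recall: float
    cohort_f1: float | None
    maternal_accuracy: float
    exact_set_rate: float
    rf_cp_nuclear: int | None = None
    nuclear_monophyly_failures: list = field(default_factory=list)
    cp_clade_failures: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for v in (
            self.cohort_precision,
            self.cohort_recall,
            self.cohort_f1,
            self.maternal_accuracy,
            self.exact_set_rate,
        ):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError("rates must lie in [0, 1]")


def evaluate_recovery(calls: list, truth: simgen.SimTruth) -> RecoveryReport:
    """Compare parentage calls against simulation truth.

    Cohort precision/recall are computed on the union of parental sets;
    maternal accuracy and exact-set rate are per-cultivar fractions.
    """
    call_ids = {c.cultivar for c in calls}
    truth_ids = set(truth.cultivars)
    if call_ids != truth_ids:
        raise ValueError(
            f"cultivar ids differ: only in calls {sorted(call_ids - truth_ids)}, "
            f"only in truth {sorted(truth_ids - call_ids)}"
        )
    inferred_union: set = set()
    true_union: set = set()
    maternal_ok = 0
    exact_ok = 0
    for call in calls:
        ct = truth.cultivars[call.cultivar]
        inferred_union |= call.parental_set
        true_union |= ct.parental_set
        if call.maternal.species == ct.maternal_species:
            maternal_ok += 1
        if call.parental_set == ct.parental_set:
            exact_ok += 1
    inter = len(inferred_union & true_union)
    precision = inter / len(inferred_union) if inferred_union else None
    recall = inter / len(true_union) if true_union else 0.0
    f1 = None
    if precision is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    n = len(calls)
    return RecoveryReport(
        cohort_precision=precision,
        cohort_recall=recall,
        cohort_f1=f1,
        maternal_accuracy=maternal_ok / n,
        exact_set_rate=exact_ok / n,
    )


# ---------------------------------------------------------------------------
# dataset loading (the on-disk layout written by simgen.write_dataset)
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    panel: simgen.SpeciesPanel
    cultivar_clones: dict  # cultivar -> locus -> list of clone strings
    cultivar_cp: dict  # cultivar -> haplotype
    truth: simgen.SimTruth | None = None


def load_dataset(input_dir: str | Path) -> Dataset:
    """Read a written dataset directory back into memory."""
    d = Path(input_dir)
    loci: dict = {}
    clones: dict = {}
    for path in sorted(d.glob("locus_*.fasta")):
        locus = path.stem.removeprefix("locus_")
        pairs = read_fasta(path)
        panel_rows = [(l, s) for l, s in pairs if l.startswith("SPECIES|")]
        labels, seqs = zip(*panel_rows)
        loci[locus] = Alignment.from_seqs(list(labels), list(seqs), locus, "nuclear")
        for lbl, seq in pairs:
            if lbl.startswith("CULTIVAR|"):
                _, cv, _clone = lbl.split("|")
                clones.setdefault(cv, {}).setdefault(locus, []).append(seq)
    if not loci:
        raise ValueError(f"no locus_*.fasta files under {d}")
    cp_pairs = read_fasta(d / "chloroplast.fasta")
    cp_haps: dict = {}
    cultivar_cp: dict = {}
    for lbl, seq in cp_pairs:
        kind, name = lbl.split("|")[:2]
        if kind == "SPECIES":
            cp_haps[name] = seq
        else:
            cultivar_cp[name] = seq
    species = sorted(cp_haps)
    panel = simgen.SpeciesPanel(
        species_ids=species, subsection_of={}, loci=loci, cp_haplotypes=cp_haps
    )
    panel.validate()
    truth = None
    truth_path = d / "truth.tsv"
    if truth_path.exists():
        truths: dict = {}
        for line in truth_path.read_text().splitlines()[1:]:
            cid, maternal, pset = line.split("\t")
            truths[cid] = simgen.CultivarTruth(
                maternal, frozenset(pset.split(";")), {}
            )
        captures = []
        cap_path = d / "capture_events.tsv"
        if cap_path.exists():
            for line in cap_path.read_text().splitlines()[1:]:
                donor, recipient = line.split("\t")
                captures.append((donor, recipient))
        truth = simgen.SimTruth(truths, captures)
    return Dataset(panel, clones, cultivar_cp, truth)


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------


@dataclass
class DiscordanceSummary:
    rf_cp_nuclear: int
    nuclear_monophyly_failures: list
    cp_clade_failures: list
    min_true_clade_support: float | None = None


@dataclass
class PipelineResult:
    config: PipelineConfig
    stats: list
    selected_nuclear: list
    nuclear_tree: tk.Tree | None = None
    cp_tree: tk.Tree | None = None
    discordance: DiscordanceSummary | None = None
    matrix: pg.ParentageMatrix | None = None
    calls: list | None = None
    summary: pg.CohortSummary | None = None
    recovery: RecoveryReport | None = None
    artifacts: list = field(default_factory=list)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("load")
def _load(cfg: PipelineConfig) -> Dataset:
    if cfg.simulation is not None:
        panel, cultivars, truth = simgen.simulate_dataset(cfg.simulation)
        clones = {cv.id: dict(cv.clones) for cv in cultivars}
        cp = {cv.id: cv.cp_haplotype for cv in cultivars}
        logger.info(
            "simulated %d species, %d loci, %d cultivars",
            len(panel.species_ids), len(panel.loci), len(cultivars),
        )
        return Dataset(panel, clones, cp, truth)
    return load_dataset(cfg.input_dir)


@_stage("markerstats")
def _marker_stage(data: Dataset) -> list:
    stats = [ms.compute_marker_stats(aln) for _, aln in sorted(data.panel.loci.items())]
    cp_aln = Alignment.from_seqs(
        [f"SPECIES|{sp}" for sp in data.panel.species_ids],
        [data.panel.cp_haplotypes[sp] for sp in data.panel.species_ids],
        locus="chloroplast",
        genome="chloroplast",
    )
    stats.append(ms.compute_marker_stats(cp_aln))
    logger.info("marker statistics computed for %d loci", len(stats))
    return stats


@_stage("trees")
def _tree_stage(data: Dataset, cfg: PipelineConfig):
    panel = data.panel
    concat = tk.concatenate([aln for _, aln in sorted(panel.loci.items())])
    nuclear_tree = tk.bootstrap_support(
        concat, builder=cfg.builder, reps=cfg.bootstrap_reps, seed=cfg.seed
    )
    # species-level trees for cyto-nuclear comparison
    rep_rows = {}
    for lbl in concat.labels:
        sp = lbl.split("|")[1]
        rep_rows.setdefault(sp, lbl)
    species = sorted(rep_rows)
    sp_nuclear = tk.neighbor_joining(
        tk.pairwise_distance(
            Alignment(
                [sp for sp in species],
                concat.take_rows(
                    [concat.labels.index(rep_rows[sp]) for sp in species]
                ).matrix,
            ),
            "JC69",
        )
    )
    cp_aln = Alignment.from_seqs(
        species, [panel.cp_haplotypes[sp] for sp in species], "cp", "chloroplast"
    )
    cp_tree = tk.neighbor_joining(tk.pairwise_distance(cp_aln, "JC69"))
    rf = tk.robinson_foulds(sp_nuclear, cp_tree)

    nuc_failures = []
    min_support: float | None = None
    by_species: dict = {}
    for lbl in concat.labels:
        by_species.setdefault(lbl.split("|")[1], set()).add(lbl)
    for sp, accs in sorted(by_species.items()):
        if not tk.is_monophyletic(nuclear_tree, accs):
            nuc_failures.append(sp)
        elif 2 <= len(accs) <= len(concat.labels) - 2:
            ref = min(tk.leaf_labels(nuclear_tree))
            side = frozenset(accs)
            if ref in side:
                side = frozenset(tk.leaf_labels(nuclear_tree)) - side
            sup = nuclear_tree.split_support.get(side)
            if sup is not None:
                min_support = sup if min_support is None else min(min_support, sup)
    cp_failures = []
    if panel.subsection_of:
        clades: dict = {}
        for sp, clade in panel.subsection_of.items():
            clades.setdefault(clade, set()).add(sp)
        for clade, members in sorted(clades.items()):
            if not tk.is_monophyletic(cp_tree, members):
                cp_failures.append(clade)
    disc = DiscordanceSummary(rf, nuc_failures, cp_failures, min_support)
    logger.info(
        "discordance: RF(cp, nuclear)=%d, nuclear monophyly failures=%s, "
        "cp clade failures=%s", rf, nuc_failures, cp_failures,
    )
    return nuclear_tree, cp_tree, disc


@_stage("parentage")
def _parentage_stage(data: Dataset, cfg: PipelineConfig, selected: list):
    refs = pg.reference_from_panel(data.panel)
    observations = []
    for cv in sorted(data.cultivar_clones):
        for locus in selected:
            clones = data.cultivar_clones[cv].get(locus)
            if clones:
                observations.append(
                    pg.dereplicate_clones(
                        clones, cfg.min_count, refs, locus, cultivar=cv
                    )
                )
    matrix = pg.build_parentage_matrix(observations, refs, cfg.max_mismatch)
    calls = pg.call_parentage(
        matrix, refs, data.cultivar_cp, cfg.cp_distance_ceiling
    )
    summary = pg.cohort_summary(calls)
    n_unmatched = sum(matrix.unmatched.values())
    logger.info(
        "parentage: %d cultivars, %d markers, parental union %s, "
        "%d unmatched haplotypes",
        len(matrix.cultivars), len(matrix.markers),
        sorted(summary.parental_union), n_unmatched,
    )
    return matrix, calls, summary


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage and (when ``cfg.out_dir`` is set) write artifacts."""
    data = _load(cfg)
    stats = _marker_stage(data)
    k = min(cfg.select_k_nuclear, sum(1 for s in stats if s.genome == "nuclear"))
    selected = ms.rank_and_select_markers(stats, k, "nuclear")
    nuclear_tree, cp_tree, disc = _tree_stage(data, cfg)
    result = PipelineResult(
        config=cfg,
        stats=stats,
        selected_nuclear=selected,
        nuclear_tree=nuclear_tree,
        cp_tree=cp_tree,
        discordance=disc,
    )
    if data.cultivar_clones:
        matrix, calls, summary = _parentage_stage(data, cfg, selected)
        result.matrix, result.calls, result.summary = matrix, calls, summary
        if data.truth is not None:
            rep = evaluate_recovery(calls, data.truth)
            rep.rf_cp_nuclear = disc.rf_cp_nuclear
            rep.nuclear_monophyly_failures = disc.nuclear_monophyly_failures
            rep.cp_clade_failures = disc.cp_clade_failures
            result.recovery = rep
    else:
        logger.info("no cultivars present: parentage stage skipped")
    if cfg.out_dir:
        _write_artifacts(result, data)
    return result


# ---------------------------------------------------------------------------
# artifact writers
# ---------------------------------------------------------------------------


def _matrix_tsv(matrix: pg.ParentageMatrix, calls: list) -> str:
    by_cv = {c.cultivar: c for c in calls}
    lines = [
        "# cell = semicolon-joined species whose reference allele is matched;"
        " empty = unmatched",
        "cultivar\t" + "\t".join(matrix.markers) + "\tcp_maternal",
    ]
    for cv in matrix.cultivars:
        cells = [
            ";".join(sorted(matrix.cells.get((cv, m), frozenset())))
            for m in matrix.markers
        ]
        maternal = by_cv[cv].maternal.species if cv in by_cv else None
        lines.append(f"{cv}\t" + "\t".join(cells) + f"\t{maternal or ''}")
    return "\n".join(lines) + "\n"


def _calls_tsv(calls: list) -> str:
    lines = [
        "# maternal_distance is the chloroplast p-distance to the assigned donor",
        "cultivar\tmaternal\tmaternal_distance\tmaternal_ties\tparental_set"
        "\tn_co_optimal\tunexplained_alleles",
    ]
    for c in calls:
        lines.append(
            "\t".join(
                [
                    c.cultivar,
                    c.maternal.species or "",
                    f"{c.maternal.distance:.6g}",
                    ";".join(c.maternal.ties),
                    ";".join(sorted(c.parental_set)),
                    str(len(c.co_optimal)),
                    str(sum(c.unexplained.values())),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def _summary_tsv(summary: pg.CohortSummary) -> str:
    lines = [
        "# per-species cultivar support counts and maternal-donor tally",
        "species\tn_cultivars_supported\tn_cultivars_maternal",
    ]
    for sp in sorted(summary.parental_union):
        lines.append(
            f"{sp}\t{summary.per_species_cultivar_counts.get(sp, 0)}"
            f"\t{summary.maternal_tally.get(sp, 0)}"
        )
    lines.append(
        f"# parental union ({len(summary.parental_union)} species): "
        + ";".join(sorted(summary.parental_union))
    )
    return "\n".join(lines) + "\n"


def _write_artifacts(result: PipelineResult, data: Dataset) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def emit(name: str, text: str) -> None:
        (out / name).write_text(text)
        result.artifacts.append(name)

    emit("markerstats.tsv", ms.stats_table(result.stats).to_csv(sep="\t", index=False))
    emit("selected_markers.txt", "\n".join(result.selected_nuclear) + "\n")
    tk.write_newick(result.nuclear_tree, out / "nuclear_tree.nwk")
    result.artifacts.append("nuclear_tree.nwk")
    tk.write_newick(result.cp_tree, out / "cp_tree.nwk")
    result.artifacts.append("cp_tree.nwk")
    d = result.discordance
    emit(
        "discordance.tsv",
        "rf_cp_nuclear\tnuclear_monophyly_failures\tcp_clade_failures"
        "\tmin_true_clade_support\n"
        f"{d.rf_cp_nuclear}\t{';'.join(d.nuclear_monophyly_failures)}"
        f"\t{';'.join(d.cp_clade_failures)}"
        f"\t{'' if d.min_true_clade_support is None else round(d.min_true_clade_support, 1)}\n",
    )
    if result.matrix is not None:
        emit("parentage_matrix.tsv", _matrix_tsv(result.matrix, result.calls))
        emit("calls.tsv", _calls_tsv(result.calls))
        emit("cohort_summary.tsv", _summary_tsv(result.summary))
    if result.recovery is not None:
        rep = result.recovery
        emit(
            "recovery.json",
            json.dumps(
                {
                    "cohort_precision": rep.cohort_precision,
                    "cohort_recall": rep.cohort_recall,
                    "cohort_f1": rep.cohort_f1,
                    "maternal_accuracy": rep.maternal_accuracy,
                    "exact_set_rate": rep.exact_set_rate,
                    "rf_cp_nuclear": rep.rf_cp_nuclear,
                    "nuclear_monophyly_failures": rep.nuclear_monophyly_failures,
                    "cp_clade_failures": rep.cp_clade_failures,
                },
                indent=2,
            )
            + "\n",
        )
    manifest = [f"seed = {result.config.seed}"]
    if result.config.simulation is not None:
        manifest.append(simgen.config_to_toml(result.config.simulation).rstrip())
    manifest.append("[artifacts]")
    manifest.extend(f"file = \"{a}\"" for a in result.artifacts)
    (out / "run_manifest.toml").write_text("\n".join(manifest) + "\n")
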