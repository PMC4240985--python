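"""Synthetic-data generator: Yule tree shape, JC expectation, zero-noise
closure, chloroplast capture bookkeeping, clone errors and dataset I/O."""

import dataclasses

import numpy as np
import pytest

from hybparent import pipeline as pl
from hybparent import simgen
from hybparent import treekit as tk
from hybparent.alignment import Alignment
from hybparent.markerstats import variable_site_count


def tip_depths(tree):
    out = {}
    for lf in tree.leaf_node_iter():
        d, node = 0.0, lf
        while node.parent_node is not None:
            d += node.edge.length
            node = node.parent_node
        out[lf.taxon.label] = d
    return out


# -- species tree -----------------------------------------------------------


def test_two_species_tree_is_ultrametric_single_topology():
    tree = simgen.simulate_species_tree(2, 1.0, seed=5)
    depths = tip_depths(tree)
    assert len(depths) == 2
    assert np.ptp(list(depths.values())) == pytest.approx(0.0, abs=1e-12)


def test_species_tree_seed_determinism_and_shape():
    t1 = simgen.simulate_species_tree(8, 1.0, seed=42)
    t2 = simgen.simulate_species_tree(8, 1.0, seed=42)
    assert t1.as_string(schema="newick") == t2.as_string(schema="newick")
    internal = sum(1 for n in t1.preorder_node_iter() if not n.is_leaf())
    assert internal == 7  # any rooted binary 8-leaf tree
    depths = list(tip_depths(t1).values())
    assert np.ptp(depths) == pytest.approx(0.0, abs=1e-9)


def test_species_tree_rejects_invalid_parameters():
    with pytest.raises(ValueError):
        simgen.simulate_species_tree(1, 1.0)
    with pytest.raises(ValueError):
        simgen.simulate_species_tree(4, 0.0)


# -- sequence evolution -----------------------------------------------------


def test_evolve_locus_rate_zero_gives_invariant_alignment():
    tree = simgen.simulate_species_tree(6, 1.0, seed=1)
    a = simgen.evolve_locus(tree, 200, 0.0, seed=2)
    assert variable_site_count(a) == 0


def test_evolve_locus_deterministic_under_seed():
    tree = simgen.simulate_species_tree(5, 1.0, seed=1)
    a1 = simgen.evolve_locus(tree, 300, 0.02, seed=9)
    a2 = simgen.evolve_locus(tree, 300, 0.02, seed=9)
    assert a1 == a2


def test_evolve_locus_unknown_model_rejected():
    tree = simgen.simulate_species_tree(4, 1.0, seed=1)
    with pytest.raises(ValueError, match="model"):
        simgen.evolve_locus(tree, 100, 0.01, model="GTR")


@pytest.mark.parametrize("model", ["JC69", "K2P"])
def test_pairwise_difference_matches_closed_form(model):
    """Two-tip tree with total path 2t: expected p-distance under JC is
    (3/4)(1 - exp(-8 t rate / 3)); K2P with kappa=1 coincides with JC."""
    rate, t, L = 0.1, 1.0, 10_000
    tree = simgen.simulate_species_tree(2, 1.0, seed=3)
    for lf in tree.leaf_node_iter():
        lf.edge.length = t
    a = simgen.evolve_locus(tree, L, rate, model=model, seed=11, kappa=1.0)
    p_obs = np.mean(a.matrix[0] != a.matrix[1])
    p_exp = 0.75 * (1 - np.exp(-8 * t * rate / 3))
    se = np.sqrt(p_exp * (1 - p_exp) / L)
    assert abs(p_obs - p_exp) < 3 * se


# -- chloroplast capture ----------------------------------------------------


def test_capture_copies_cp_and_leaves_nuclear_untouched(small_cfg):
    panel = simgen.build_species_panel(small_cfg)
    donor, recipient = panel.species_ids[0], panel.species_ids[-1]
    panel2 = simgen.apply_chloroplast_capture(panel, donor, recipient)
    assert panel2.cp_haplotypes[recipient] == panel2.cp_haplotypes[donor]
    assert panel.cp_haplotypes[recipient] != panel.cp_haplotypes[donor]
    for locus in panel.loci:
        assert panel2.loci[locus] == panel.loci[locus]
    assert panel2.capture_events == [(donor, recipient)]
    assert panel.capture_events == []


def test_capture_validates_species():
    cfg = simgen.SimConfig(n_species=4, n_nuclear_loci=2, n_cultivars=0,
                           parental_pool_size=2, seed=1)
    panel = simgen.build_species_panel(cfg)
    with pytest.raises(KeyError):
        simgen.apply_chloroplast_capture(panel, "nope", panel.species_ids[0])
    with pytest.raises(ValueError):
        simgen.apply_chloroplast_capture(
            panel, panel.species_ids[0], panel.species_ids[0]
        )


def test_cross_clade_capture_creates_cytonuclear_discordance(small_cfg):
    panel = simgen.build_species_panel(small_cfg)
    donor, recipient, clade = simgen.select_discordance_probe(panel)
    assert donor not in clade and recipient in clade
    panel2 = simgen.apply_chloroplast_capture(panel, donor, recipient)
    species = panel2.species_ids

    def species_tree_from(seqs):
        return tk.neighbor_joining(
            tk.pairwise_distance(Alignment.from_seqs(species, seqs), "JC69")
        )

    cp_tree = species_tree_from([panel2.cp_haplotypes[s] for s in species])
    concat = tk.concatenate(list(panel2.loci.values()))
    first_acc = {lbl.split("|")[1]: lbl for lbl in reversed(concat.labels)}
    nuc_tree = species_tree_from(
        [concat.row(first_acc[s]) for s in species]
    )
    assert tk.robinson_foulds(cp_tree, nuc_tree) > 0
    assert not tk.is_monophyletic(cp_tree, clade)
    assert tk.is_monophyletic(nuc_tree, clade)


# -- cultivars and clones ---------------------------------------------------


def test_zero_noise_closure_every_allele_copies_origin(small_dataset):
    panel, cultivars, truth = small_dataset
    for cv in cultivars:
        ct = truth.cultivars[cv.id]
        assert ct.maternal_species in ct.parental_set
        assert cv.cp_haplotype == panel.cp_haplotypes[ct.maternal_species]
        for locus, pair in cv.alleles.items():
            for seq, origin in pair:
                assert origin in ct.parental_set
                panel_alleles = [
                    panel.loci[locus].sequence(i)
                    for i, lbl in enumerate(panel.loci[locus].labels)
                    if lbl.split("|")[1] == origin
                ]
                assert seq in panel_alleles


def test_single_parent_config_forces_both_alleles(small_cfg):
    cfg = dataclasses.replace(
        small_cfg, parental_set_sizes=((1, 1.0),), n_cultivars=4
    )
    panel = simgen.build_species_panel(cfg)
    cultivars, truth = simgen.generate_cultivars(panel, cfg)
    for cv in cultivars:
        ct = truth.cultivars[cv.id]
        assert len(ct.parental_set) == 1
        (only,) = ct.parental_set
        for pair in cv.alleles.values():
            assert {origin for _, origin in pair} == {only}


def test_sample_clones_no_error_copies_inputs():
    a, b = "ACGTACGT", "ACGTACGA"
    clones = simgen.sample_clones((a, b), 16, 0.0, seed=4)
    assert len(clones) == 16
    assert set(clones) <= {a, b}
    same = simgen.sample_clones((a, a), 8, 0.0, seed=4)
    assert set(same) == {a}


def test_clone_error_rate_matches_binomial_expectation():
    L, rate, n_clones, reps = 1000, 0.01, 16, 200
    allele = "ACGT" * (L // 4)
    ref = np.frombuffer(allele.encode(), dtype=np.uint8)
    errs = []
    for seed in range(reps):
        for clone in simgen.sample_clones((allele, allele), n_clones, rate, seed):
            arr = np.frombuffer(clone.encode(), dtype=np.uint8)
            errs.append(int((arr != ref).sum()))
    mean = np.mean(errs)
    expect = L * rate
    se = np.sqrt(L * rate * (1 - rate) / len(errs))
    assert abs(mean - expect) < 3 * se


def test_dataset_seed_determinism(small_cfg):
    p1, c1, t1 = simgen.simulate_dataset(small_cfg)
    p2, c2, t2 = simgen.simulate_dataset(small_cfg)
    assert p1.cp_haplotypes == p2.cp_haplotypes
    for locus in p1.loci:
        assert p1.loci[locus] == p2.loci[locus]
    assert [cv.clones for cv in c1] == [cv.clones for cv in c2]
    assert t1.cultivars.keys() == t2.cultivars.keys()


# -- dataset writer ---------------------------------------------------------


def test_write_dataset_round_trips_and_counts(tmp_path, small_cfg, small_dataset):
    panel, cultivars, truth = small_dataset
    manifest = simgen.write_dataset(panel, cultivars, truth, tmp_path, small_cfg)
    assert len(manifest["fasta_files"]) == small_cfg.n_nuclear_loci + 1
    truth_rows = (tmp_path / manifest["truth"]).read_text().splitlines()
    assert len(truth_rows) - 1 == small_cfg.n_cultivars

    data = pl.load_dataset(tmp_path)
    assert data.panel.cp_haplotypes == panel.cp_haplotypes
    for locus in panel.loci:
        assert data.panel.loci[locus] == panel.loci[locus]
    assert data.truth is not None
    for cid, ct in truth.cultivars.items():
        assert data.truth.cultivars[cid].maternal_species == ct.maternal_species
        assert data.truth.cultivars[cid].parental_set == ct.parental_set
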