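"""Combinatorial correctness of the assembly-network enumeration."""

import pytest

from capscaffold.network import (
    AssemblyConstraints,
    ComplexSpecies,
    add_translation_stage,
    canonical_label,
    enumerate_species,
    free_monomer,
    full_complex_label,
    generate_network,
)

from oracles import closed_form_pairs, closed_form_species, grow_network

LIGANDS = ("A", "E", "D", "P")


@pytest.mark.parametrize("n", range(5))
def test_counts_match_brute_force_oracle_and_closed_forms(n):
    """Species and reversible-pair counts agree with an independent
    graph-growing enumeration and with the closed forms for 0-4 ligands."""
    species, forward = grow_network(LIGANDS[:n])
    net = generate_network(n)
    assert len(species) == closed_form_species(n) == net.n_species
    assert len(forward) == closed_form_pairs(n) == net.n_reversible_pairs
    assert net.n_irreversible == 2 * net.n_reversible_pairs


def test_four_ligand_class_tally(full_network):
    """Forward reactions split 180/180/216/296 over the four binding classes."""
    tally = full_network.class_tally()
    assert tally["bind_free_to_G"] == 180
    assert tally["bind_free_to_R"] == 180
    assert tally["bridge_association"] == 216
    assert tally["ring_closure"] == 296
    # one reverse per forward, by class
    assert tally["unbind_terminal"] == 360
    assert tally["unbind_fission"] == 216
    assert tally["unbind_in_ring"] == 296


def test_every_forward_has_exactly_one_reverse(full_network):
    reverse_targets = [r.reverse_of for r in full_network.reactions
                       if r.reverse_of is not None]
    assert len(reverse_targets) == len(set(reverse_targets)) == 872
    for r in full_network.reactions:
        if r.reverse_of is not None:
            fwd = full_network.reactions[r.reverse_of]
            assert sorted(fwd.reactants) == sorted(r.products)
            assert sorted(fwd.products) == sorted(r.reactants)


def test_reactions_are_molecule_balanced(final_network):
    final_network.check_balance()  # raises on violation


def test_all_species_reachable_from_free_monomers(full_network):
    """Breadth-first closure over the reactions covers every species."""
    reached = {free_monomer(m).label for m in ("G", "R") + full_network.ligands}
    changed = True
    while changed:
        changed = False
        for r in full_network.reactions:
            if all(lab in reached for lab in r.reactants):
                for lab in r.products:
                    if lab not in reached:
                        reached.add(lab)
                        changed = True
    assert reached == {s.label for s in full_network.species}


def test_canonical_labels():
    assert free_monomer("G").label == "G()"
    assert free_monomer("A").label == "A(free)"
    bridged_E = ComplexSpecies(True, True, (("E", "gr"),))
    assert canonical_label(bridged_E) == "G.R.E(gr)"
    # construction order does not matter for structurally identical species
    s1 = ComplexSpecies(True, True, (("A", "g"), ("E", "gr")))
    s2 = ComplexSpecies(True, True, tuple(reversed((("A", "g"), ("E", "gr")))))
    assert canonical_label(s1) == canonical_label(s2)


def test_labels_injective_and_monomers_first(final_network):
    labels = [s.label for s in final_network.species]
    assert len(set(labels)) == 215
    assert labels[:6] == ["G()", "R()", "A(free)", "E(free)", "D(free)", "P(free)"]
    body = labels[6:211]
    assert body == sorted(body)


def test_species_invariants_reject_malformed_complexes():
    with pytest.raises(ValueError):  # duplicate molecule
        ComplexSpecies(True, False, (("A", "g"), ("A", "g")))
    with pytest.raises(ValueError):  # bound to absent scaffold
        ComplexSpecies(True, False, (("A", "r"),))
    with pytest.raises(ValueError):  # G+R with no bridging ligand: disconnected
        ComplexSpecies(True, True, (("A", "g"), ("E", "r")))


def test_unsupported_constraints_rejected():
    with pytest.raises(ValueError, match="unsupported constraint"):
        enumerate_species(2, AssemblyConstraints(single_copy=False))
    with pytest.raises(ValueError, match="unsupported constraint"):
        generate_network(2, AssemblyConstraints(allow_scaffold_bond=True))


def test_translation_stage_augmentation(full_network, final_network, toy_network):
    assert final_network.counts == {"n_species": 215, "n_irreversible": 1746,
                                    "n_reversible_pairs": 872}
    assert toy_network.counts == {"n_species": 10, "n_irreversible": 10,
                                  "n_reversible_pairs": 4}
    with pytest.raises(ValueError, match="already present"):
        add_translation_stage(final_network)
    init = final_network.reactions[-2]
    assert init.reactants == (full_complex_label(LIGANDS), "S43")
    assert set(init.products) == {"EL", "G()", "A(free)", "E(free)",
                                  "D(free)", "P(free)"}
    elong = final_network.reactions[-1]
    assert (elong.reactants, set(elong.products)) == (("EL",), {"S40", "PEP", "R()"})
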