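"""Rule-based enumeration of the random-order cap-binding-complex assembly network.

Two scaffolds -- eIF4G (``G``) and mRNA (``R``) -- each carry one dedicated
binding site per ligand.  Four ligands -- eIF4A (``A``), eIF4E (``E``),
Ded1 (``D``) and Pab1 (``P``) -- each carry one G-facing and one R-facing
site, so a ligand can be bound to G, to R, or bridge both scaffolds.
Complexes obey three structural constraints:

* at most one copy of each molecule per complex (single-copy rule),
* no direct scaffold-scaffold (G-R) bond,
* the bond graph is connected.

Expanding every binding reaction compatible with these rules over four
ligands yields 211 species and 872 reversible binding reactions (1744
irreversible); two further reactions hand the fully assembled complex to a
43S pre-initiation pool and recycle the elongating ribosome, giving the
final 215-species / 1746-reaction model.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

SCAFFOLDS = ("G", "R")
DEFAULT_LIGANDS = ("A", "E", "D", "P")
STAGE_SPECIES = ("S43", "EL", "S40", "PEP")

#: bond states a ligand can be in within a complex
LIGAND_STATES = ("free", "g", "r", "gr")

MOLECULE_ORDER = SCAFFOLDS + DEFAULT_LIGANDS + STAGE_SPECIES


@dataclass(frozen=True)
class MoleculeKind:
    """A molecule type: scaffold, ligand or translation-stage species."""

    name: str
    role: str  # "scaffold" | "ligand" | "stage"
    sites: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role == "ligand" and len(self.sites) != 2:
            raise ValueError(f"ligand {self.name} must have exactly two sites")
        if self.role == "stage" and self.sites:
            raise ValueError(f"stage species {self.name} has no sites")


def molecule_kinds(ligands: tuple[str, ...] = DEFAULT_LIGANDS) -> dict[str, MoleculeKind]:
    """The molecule inventory: scaffolds with one site per ligand, two-site ligands."""
    kinds = {
        "G": MoleculeKind("G", "scaffold", tuple(f"g_{x}" for x in ligands)),
        "R": MoleculeKind("R", "scaffold", tuple(f"r_{x}" for x in ligands)),
    }
    for x in ligands:
        kinds[x] = MoleculeKind(x, "ligand", (f"{x}_g", f"{x}_r"))
    for s in STAGE_SPECIES:
        kinds[s] = MoleculeKind(s, "stage")
    return kinds


@dataclass(frozen=True)
class AssemblyConstraints:
    """Structural rules of the assembly grammar.

    Only the single-copy / no-scaffold-bond grammar is supported; it is the
    grammar under which the rule expansion gives the published network sizes.
    """

    single_copy: bool = True
    allow_scaffold_bond: bool = False

    def validate(self) -> None:
        if not self.single_copy:
            raise ValueError("unsupported constraint: multi-copy complexes are not supported")
        if self.allow_scaffold_bond:
            raise ValueError("unsupported constraint: direct scaffold-scaffold bonds are not supported")


@dataclass(frozen=True, order=True)
class ComplexSpecies:
    """A connected scaffold/ligand complex (or a free monomer, or a stage species).

    The state is fully described by scaffold presence plus each present
    ligand's bond state: ``g`` (bound to eIF4G only), ``r`` (bound to mRNA
    only) or ``gr`` (bridging both).  A lone unbound ligand is its own
    species with state ``free``.
    """

    has_G: bool
    has_R: bool
    ligands: tuple[tuple[str, str], ...]  # ((name, state), ...) in ligand order
    stage: str | None = None  # name of a stage species, exclusive of the rest

    def __post_init__(self) -> None:
        if self.stage is not None:
            if self.has_G or self.has_R or self.ligands:
                raise ValueError("stage species carry no scaffolds or ligands")
            return
        names = [x for x, _ in self.ligands]
        if len(set(names)) != len(names):
            raise ValueError("single-copy rule violated")
        states = dict(self.ligands)
        if any(s not in LIGAND_STATES for s in states.values()):
            raise ValueError("invalid bond state")
        if "free" in states.values():
            if len(self.ligands) != 1 or self.has_G or self.has_R:
                raise ValueError("a free ligand is a monomeric species")
        for x, s in self.ligands:
            if "g" in s and not self.has_G and s != "free":
                raise ValueError(f"{x} bound to absent G")
            if s in ("r", "gr") and not self.has_R:
                raise ValueError(f"{x} bound to absent R")
        if not self._connected():
            raise ValueError("bond graph not connected")

    def _connected(self) -> bool:
        if self.has_G and self.has_R:
            # G and R only connect through a bridging ligand
            return any(s == "gr" for _, s in self.ligands)
        # single-scaffold complexes and monomers are trivially connected
        return True

    # -- views ------------------------------------------------------------

    @property
    def members(self) -> frozenset[str]:
        """Molecule names present in the complex."""
        if self.stage is not None:
            return frozenset({self.stage})
        out = set(x for x, _ in self.ligands)
        if self.has_G:
            out.add("G")
        if self.has_R:
            out.add("R")
        return frozenset(out)

    @property
    def bonds(self) -> frozenset[tuple[str, str]]:
        """Bonds as (ligand site, scaffold site) pairs."""
        out = set()
        for x, s in self.ligands:
            if "g" in s and s != "free":
                out.add((f"{x}_g", f"g_{x}"))
            if "r" in s:
                out.add((f"{x}_r", f"r_{x}"))
        return frozenset(out)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def size(self) -> int:
        return len(self.members)

    def state_of(self, ligand: str) -> str | None:
        return dict(self.ligands).get(ligand)

    @property
    def composition(self) -> frozenset[tuple[str, int]]:
        """Molecule-balance tokens; stage species share one ribosome token,
        EL additionally carries the mRNA it is translating, PEP is exempt."""
        if self.stage is not None:
            return frozenset({
                "S43": (("RIB", 1),),
                "S40": (("RIB", 1),),
                "EL": (("RIB", 1), ("R", 1)),
                "PEP": (),
            }[self.stage])
        toks = [(x, 1) for x in sorted(self.members)]
        return frozenset(toks)

    @property
    def label(self) -> str:
        return canonical_label(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def canonical_label(species: ComplexSpecies) -> str:
    """Deterministic, injective text name.

    Molecules are listed in the fixed order G, R, A, E, D, P joined by
    ``.``; scaffolds appear bare, each ligand is annotated with its bond
    state, e.g. ``G()``, ``G.R.E(gr)``, ``A(free)``.
    """
    if species.stage is not None:
        return species.stage
    in_complex = bool(species.ligands)
    parts = []
    if species.has_G:
        parts.append("G" if in_complex else "G()")
    if species.has_R:
        parts.append("R" if in_complex else "R()")
    order = {x: i for i, x in enumerate(DEFAULT_LIGANDS)}
    for x, s in sorted(species.ligands, key=lambda t: order.get(t[0], 99)):
        parts.append(f"{x}({s})")
    return ".".join(parts)


def free_monomer(name: str) -> ComplexSpecies:
    if name == "G":
        return ComplexSpecies(True, False, ())
    if name == "R":
        return ComplexSpecies(False, True, ())
    return ComplexSpecies(False, False, ((name, "free"),))


def _ligand_names(n_ligands: int) -> tuple[str, ...]:
    if n_ligands < 0:
        raise ValueError("n_ligands must be >= 0")
    if n_ligands <= len(DEFAULT_LIGANDS):
        return DEFAULT_LIGANDS[:n_ligands]
    return DEFAULT_LIGANDS + tuple(f"L{i}" for i in range(5, n_ligands + 1))


def enumerate_species(
    n_ligands: int, constraints: AssemblyConstraints | None = None
) -> list[ComplexSpecies]:
    """Every connected complex the grammar admits, free monomers included.

    Free monomers come first (G, R, then ligands); all other species follow
    in lexicographic order of their canonical label.  For ``n`` ligands the
    count is ``n + 2^(n+1) + 4^n - 3^n`` (211 at n = 4).
    """
    (constraints or AssemblyConstraints()).validate()
    ligands = _ligand_names(n_ligands)
    monomers = [free_monomer("G"), free_monomer("R")] + [free_monomer(x) for x in ligands]

    complexes: list[ComplexSpecies] = []
    # single-scaffold complexes: any non-empty ligand subset, all bound to it
    for has_G in (True, False):
        state = "g" if has_G else "r"
        for k in range(1, len(ligands) + 1):
            for subset in itertools.combinations(ligands, k):
                complexes.append(
                    ComplexSpecies(has_G, not has_G, tuple((x, state) for x in subset))
                )
    # double-scaffold complexes: each ligand absent/g/r/gr, at least one bridge
    for states in itertools.product((None, "g", "r", "gr"), repeat=len(ligands)):
        if "gr" not in states:
            continue
        ligs = tuple((x, s) for x, s in zip(ligands, states) if s is not None)
        complexes.append(ComplexSpecies(True, True, ligs))

    complexes.sort(key=canonical_label)
    return monomers + complexes


@dataclass(frozen=True)
class Reaction:
    """A single irreversible reaction between enumerated species."""

    reactants: tuple[str, ...]  # canonical labels, 1-2 entries
    products: tuple[str, ...]  # 1-6 entries
    rate_param: str
    rxn_class: str
    reverse_of: int | None = None  # index of the paired forward reaction

    def __post_init__(self) -> None:
        if not 1 <= len(self.reactants) <= 2:
            raise ValueError("reactions have 1-2 reactants")
        if not 1 <= len(self.products) <= 6:
            raise ValueError("reactions have 1-6 products")


@dataclass
class ReactionNetwork:
    """Species list plus mass-balanced reactions with forward/reverse pairing."""

    species: list[ComplexSpecies]
    reactions: list[Reaction]
    ligands: tuple[str, ...]
    has_translation_stage: bool = False
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {s.label: i for i, s in enumerate(self.species)}
        if len(self._index) != len(self.species):
            raise ValueError("canonical labels are not injective")

    def species_index(self, label: str) -> int:
        return self._index[label]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_irreversible(self) -> int:
        return len(self.reactions)

    @property
    def n_reversible_pairs(self) -> int:
        return sum(1 for r in self.reactions if r.reverse_of is not None)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "n_species": self.n_species,
            "n_irreversible": self.n_irreversible,
            "n_reversible_pairs": self.n_reversible_pairs,
        }

    def class_tally(self) -> dict[str, int]:
        tally: dict[str, int] = {}
        for r in self.reactions:
            tally[r.rxn_class] = tally.get(r.rxn_class, 0) + 1
        return tally

    def check_balance(self) -> None:
        """Molecule-kind balance for every reaction (PEP is exempt by its
        empty composition)."""
        comp = {s.label: dict(s.composition) for s in self.species}

        def total(labels: tuple[str, ...]) -> dict[str, int]:
            out: dict[str, int] = {}
            for lab in labels:
                for tok, n in comp[lab].items():
                    out[tok] = out.get(tok, 0) + n
            return out

        for i, r in enumerate(self.reactions):
            if total(r.reactants) != total(r.products):
                raise AssertionError(f"reaction {i} is not molecule-balanced: {r}")

    def summary_rows(self) -> list[dict]:
        return [
            {"label": s.label, "size": s.size, "n_bonds": s.n_bonds}
            for s in self.species
        ]

    def counts_json(self) -> str:
        rec = dict(self.counts)
        rec["class_tally"] = self.class_tally()
        rec["n_ligands"] = len(self.ligands)
        return json.dumps(rec, indent=2)


def _with_ligand(sp: ComplexSpecies, ligand: str, state: str) -> ComplexSpecies:
    order = {x: i for i, x in enumerate(_ligand_names(6))}
    ligs = dict(sp.ligands)
    ligs[ligand] = state
    new = tuple(sorted(ligs.items(), key=lambda t: order.get(t[0], 99)))
    return ComplexSpecies(sp.has_G, sp.has_R, new)


def _without_ligand(sp: ComplexSpecies, ligand: str) -> ComplexSpecies:
    ligs = tuple((x, s) for x, s in sp.ligands if x != ligand)
    return ComplexSpecies(sp.has_G, sp.has_R, ligs)


def generate_network(
    n_ligands: int, constraints: AssemblyConstraints | None = None
) -> ReactionNetwork:
    """Expand all binding reactions over the enumerated species.

    Four forward classes are emitted, each with exactly one reverse:

    * ``bind_free_to_G`` / ``bind_free_to_R`` -- a free ligand binds a
      complex containing that scaffold and lacking the ligand; reversed by
      ``unbind_terminal``.
    * ``bridge_association`` -- a ligand singly bound in a G-only complex
      binds the R of an R-only complex with disjoint ligand content (or the
      mirror image); reversed by ``unbind_fission``.
    * ``ring_closure`` -- a singly tethered ligand in a G+R complex forms
      its second, intramolecular bond; reversed by ``unbind_in_ring``.
    """
    (constraints or AssemblyConstraints()).validate()
    ligands = _ligand_names(n_ligands)
    species = enumerate_species(n_ligands, constraints)
    labels = {s.label for s in species}
    reactions: list[Reaction] = []

    def add_pair(fwd: Reaction, rev_reactants, rev_products, rev_param, rev_class):
        for lab in fwd.reactants + fwd.products + tuple(rev_reactants) + tuple(rev_products):
            if lab not in labels:
                raise AssertionError(f"reaction references unknown species {lab}")
        reactions.append(fwd)
        reactions.append(
            Reaction(tuple(rev_reactants), tuple(rev_products), rev_param, rev_class,
                     reverse_of=len(reactions) - 1)
        )

    g_only = [s for s in species if s.has_G and not s.has_R]
    r_only = [s for s in species if s.has_R and not s.has_G]
    both = [s for s in species if s.has_G and s.has_R]

    for x in ligands:
        free_x = free_monomer(x).label
        # free ligand onto a scaffold-containing complex lacking it
        for scaffold, state, pool in (("G", "g", g_only + both), ("R", "r", r_only + both)):
            for sp in pool:
                if sp.state_of(x) is not None:
                    continue
                prod = _with_ligand(sp, x, state)
                add_pair(
                    Reaction((free_x, sp.label), (prod.label,),
                             f"kon_{scaffold}[{x}]", f"bind_free_to_{scaffold}"),
                    (prod.label,), (free_x, sp.label),
                    f"koff_{scaffold}[{x}]", "unbind_terminal",
                )
        # bimolecular bridging: x singly bound on one scaffold binds the other
        for cg in g_only:
            if cg.state_of(x) != "g":
                continue
            for cr in r_only:
                if cr.state_of(x) is not None:
                    continue
                if {n for n, _ in cg.ligands} & {n for n, _ in cr.ligands}:
                    continue  # single-copy rule: partners must be disjoint
                merged = ComplexSpecies(
                    True, True,
                    tuple(sorted(
                        [(n, "gr" if n == x else s) for n, s in cg.ligands]
                        + [(n, s) for n, s in cr.ligands],
                        key=lambda t: ligands.index(t[0]),
                    )),
                )
                add_pair(
                    Reaction((cg.label, cr.label), (merged.label,),
                             f"kon_R[{x}]", "bridge_association"),
                    (merged.label,), (cg.label, cr.label),
                    f"koff_R[{x}]", "unbind_fission",
                )
        for cr in r_only:
            if cr.state_of(x) != "r":
                continue
            for cg in g_only:
                if cg.state_of(x) is not None:
                    continue
                if {n for n, _ in cg.ligands} & {n for n, _ in cr.ligands}:
                    continue
                merged = ComplexSpecies(
                    True, True,
                    tuple(sorted(
                        [(n, s) for n, s in cg.ligands]
                        + [(n, "gr" if n == x else s) for n, s in cr.ligands],
                        key=lambda t: ligands.index(t[0]),
                    )),
                )
                add_pair(
                    Reaction((cr.label, cg.label), (merged.label,),
                             f"kon_G[{x}]", "bridge_association"),
                    (merged.label,), (cr.label, cg.label),
                    f"koff_G[{x}]", "unbind_fission",
                )
        # intramolecular ring closure of a singly tethered ligand
        for sp in both:
            st = sp.state_of(x)
            if st not in ("g", "r"):
                continue
            closed = _with_ligand(sp, x, "gr")
            kc = "kc_R" if st == "g" else "kc_G"  # rate of the bond being formed
            add_pair(
                Reaction((sp.label,), (closed.label,), f"{kc}[{x}]", "ring_closure"),
                (closed.label,), (sp.label,),
                f"koff_bridge[{x}]", "unbind_in_ring",
            )

    net = ReactionNetwork(species, reactions, ligands)
    net.check_balance()
    return net


def full_complex_label(ligands: tuple[str, ...]) -> str:
    """The translation-competent species: all ligands bridging G and R."""
    return ComplexSpecies(True, True, tuple((x, "gr") for x in ligands)).label


def add_translation_stage(network: ReactionNetwork) -> ReactionNetwork:
    """Append the two reactions standing in for the rest of translation.

    The fully assembled complex binds a 43S pre-initiation complex, releasing
    the factors and creating an elongating ribosome; the elongating ribosome
    resolves into a free 40S subunit, a peptide and the free mRNA.  Adds the
    four stage species (S43, EL, S40, PEP) and exactly two reactions.
    """
    if network.has_translation_stage:
        raise ValueError("translation stage already present")
    full = full_complex_label(network.ligands)
    try:
        network.species_index(full)
    except KeyError:
        raise ValueError(f"fully assembled complex {full!r} absent from network") from None

    species = list(network.species) + [
        ComplexSpecies(False, False, (), stage=s) for s in STAGE_SPECIES
    ]
    frees = [free_monomer("G").label] + [free_monomer(x).label for x in network.ligands]
    reactions = list(network.reactions) + [
        Reaction((full, "S43"), ("EL", *frees), "k_init", "initiate_43S"),
        Reaction(("EL",), ("S40", "PEP", free_monomer("R").label), "k_elong",
                 "complete_elongation"),
    ]
    net = ReactionNetwork(species, reactions, network.ligands, has_translation_stage=True)
    net.check_balance()
    return net
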