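"""Independent brute-force oracles used by the test suite.

Deliberately different representations and algorithms from the package:
complexes are explicit (members, bond-set) graphs grown breadth-first from
the free monomers, and the toy ODE right-hand side is written out by hand.
"""

from __future__ import annotations

import itertools

import numpy as np

SCAFFOLDS = ("G", "R")


def _valid(members: frozenset, bonds: frozenset) -> bool:
    ligs = members - set(SCAFFOLDS)
    for x, s in bonds:
        if x not in members or s not in members:
            return False
    if len(members) > 1:
        # connectivity via union-find over bond edges
        parent = {m: m for m in members}

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for x, s in bonds:
            parent[find(x)] = find(s)
        if len({find(m) for m in members}) != 1:
            return False
    return True


def grow_network(ligands: tuple[str, ...]):
    """Breadth-first closure of binding moves starting from free monomers.

    Returns (species set, forward reaction set).  A state is
    (frozenset members, frozenset of (ligand, scaffold) bonds); a forward
    reaction is (frozenset reactant states, product state).
    """
    monomers = [frozenset({m}) for m in SCAFFOLDS + tuple(ligands)]
    species = {(m, frozenset()) for m in monomers}
    reactions = set()
    frontier = list(species)
    while frontier:
        new_states = set()

        def emit(reactants, product):
            if not _valid(*product):
                return
            reactions.add((frozenset(reactants), product))
            if product not in species:
                new_states.add(product)

        pool = list(species)
        # bimolecular joins: ligand X in c1 gains a bond to scaffold S in c2
        for c1, c2 in itertools.product(pool, pool):
            m1, b1 = c1
            m2, b2 = c2
            if m1 & m2:
                continue
            for x in m1 - set(SCAFFOLDS):
                for s in SCAFFOLDS:
                    if s in m2 and (x, s) not in b1:
                        emit([c1, c2], (m1 | m2, b1 | b2 | {(x, s)}))
        # intramolecular closures
        for c in pool:
            m, b = c
            for x in m - set(SCAFFOLDS):
                for s in SCAFFOLDS:
                    if s in m and (x, s) not in b:
                        emit([c], (m, b | {(x, s)}))
        species |= new_states
        frontier = list(new_states)
    return species, reactions


def closed_form_species(n: int) -> int:
    return n + 2 ** (n + 1) + 4 ** n - 3 ** n


def closed_form_pairs(n: int) -> int:
    if n == 0:
        return 0
    return n * (2 ** n + 4 ** n - 2 * 3 ** (n - 1))


def toy_rhs(x: dict[str, float], p: dict[str, float]) -> dict[str, float]:
    """Hand-written ODEs for the one-ligand (10-species) augmented model.

    Species keys: G, R, A, GA, RA, GRA, S43, EL, S40, PEP (S43/S40 buffered).
    """
    v_bind_g = p["kon_G"] * x["A"] * x["G"]
    v_unb_g = p["koff_G"] * x["GA"]
    v_bind_r = p["kon_R"] * x["A"] * x["R"]
    v_unb_r = p["koff_R"] * x["RA"]
    v_brid_g = p["kon_R"] * x["GA"] * x["R"]   # GA + R -> GRA (forms A-R bond)
    v_fiss_g = p["koff_R"] * x["GRA"]
    v_brid_r = p["kon_G"] * x["RA"] * x["G"]   # RA + G -> GRA (forms A-G bond)
    v_fiss_r = p["koff_G"] * x["GRA"]
    v_init = p["k_init"] * x["GRA"] * x["S43"]
    v_elong = p["k_elong"] * x["EL"]
    return {
        "G": -v_bind_g + v_unb_g - v_brid_r + v_fiss_r + v_init,
        "R": -v_bind_r + v_unb_r - v_brid_g + v_fiss_g + v_elong,
        "A": -v_bind_g + v_unb_g - v_bind_r + v_unb_r + v_init,
        "GA": v_bind_g - v_unb_g - v_brid_g + v_fiss_g,
        "RA": v_bind_r - v_unb_r - v_brid_r + v_fiss_r,
        "GRA": v_brid_g - v_fiss_g + v_brid_r - v_fiss_r - v_init,
        "S43": 0.0,
        "EL": v_init - v_elong,
        "S40": 0.0,
        "PEP": v_elong,
    }


def rk4_integrate(rhs, x0: np.ndarray, t_end: float, dt: float) -> np.ndarray:
    """Fixed-step classical Runge-Kutta, the reference integrator."""
    x = x0.astype(float).copy()
    n_steps = int(round(t_end / dt))
    for _ in range(n_steps):
        k1 = rhs(x)
        k2 = rhs(x + 0.5 * dt * k1)
        k3 = rhs(x + 0.5 * dt * k2)
        k4 = rhs(x + dt * k3)
        x = x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return x
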