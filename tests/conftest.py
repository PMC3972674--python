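import itertools

import numpy as np
import pytest

from spatialrules import GeometrySpec, WorldState, parse_model
from spatialrules.model import UNBOUND, BOUND_ANY, WILD

TOY_MODEL = """\
begin molecule types
  A(a,a,b~none~mod)
end molecule types
begin reaction rules
  poly: A(a) + A(a) -> A(a!1).A(a!1) 1.0
end reaction rules
"""


@pytest.fixture
def toy_model():
    return parse_model(TOY_MODEL)


@pytest.fixture
def toy_geometry():
    return {"A": GeometrySpec("A", mass=15.0, radius=10.0)}


def make_world(model, geometry, n, box_side=400.0):
    half = box_side / 2.0
    world = WorldState(model, geometry, box=((-half, half),) * 3, seed=0)
    rng = np.random.default_rng(1234 + n)
    for _ in range(n):
        world.add_molecule("A", rng.uniform(-half, half, size=3))
    return world


def randomize_world(world, rng, bond_fraction=0.5, mod_fraction=0.3):
    """Randomly bond free a-site pairs and set b-site modification labels."""
    a_sites = [s for i in range(world.n_particles) for s in world.particle_sites(i)
               if world.site_name(s) == "a"]
    rng.shuffle(a_sites)
    while len(a_sites) >= 2:
        s1 = a_sites.pop()
        if rng.random() > bond_fraction:
            continue
        # avoid bonding two sites of the same particle
        cands = [s for s in a_sites if world.site_owner(s) != world.site_owner(s1)]
        if not cands:
            continue
        s2 = cands[rng.integers(len(cands))]
        a_sites.remove(s2)
        world.form_bond(s1, s2)
    for i in range(world.n_particles):
        for s in world.particle_sites(i):
            if world.site_name(s) == "b" and rng.random() < mod_fraction:
                world.set_mod(s, "mod")
    return world


# ---------------------------------------------------------------------------
# Independent brute-force matching oracle: enumerate ALL injective
# assignments of pattern molecules to particles and pattern sites to site
# occurrences, then filter by the constraints.  Kept deliberately naive.
# ---------------------------------------------------------------------------

def brute_force_match(patterns, world, dedup=True):
    if not isinstance(patterns, (list, tuple)):
        patterns = (patterns,)
    mols = [(ci, mi, m) for ci, cp in enumerate(patterns)
            for mi, m in enumerate(cp.molecules)]
    n = len(mols)
    results = []
    seen = set()
    for perm in itertools.permutations(range(world.n_particles), n):
        if any(world.particle_type(p).name != m.type_name
               for (_, _, m), p in zip(mols, perm)):
            continue
        site_choices = []
        ok = True
        for (_, _, m), p in zip(mols, perm):
            world_sites = list(world.particle_sites(p))
            options = []
            for assign in itertools.permutations(world_sites, len(m.sites)):
                good = True
                for sp, ws in zip(m.sites, assign):
                    if world.site_name(ws) != sp.site_name:
                        good = False
                        break
                    partner = world.site_partner(ws)
                    if sp.bond is UNBOUND and partner != -1:
                        good = False
                        break
                    if sp.bond is BOUND_ANY and partner == -1:
                        good = False
                        break
                    if isinstance(sp.bond, int) and partner == -1:
                        good = False
                        break
                    if sp.mod is not None and world.site_mod(ws) != sp.mod:
                        good = False
                        break
                if good:
                    options.append(assign)
            if not options:
                ok = False
                break
            site_choices.append(options)
        if not ok:
            continue
        for combo in itertools.product(*site_choices):
            # bond-label consistency within each complex pattern
            label_map = {}
            good = True
            for (ci, mi, m), assign in zip(mols, combo):
                for sp, ws in zip(m.sites, assign):
                    if isinstance(sp.bond, int):
                        label_map.setdefault((ci, sp.bond), []).append(ws)
            for ends in label_map.values():
                if len(ends) == 2:
                    if world.site_partner(ends[0]) != ends[1]:
                        good = False
                        break
                elif len(ends) == 1:
                    pass  # half a bond label cannot be checked; patterns are valid so this is unreachable
            if not good:
                continue
            if dedup:
                key = []
                for (ci, mi, m), p, assign in zip(mols, perm, combo):
                    sig = (m.type_name,
                           tuple(sorted((sp.site_name, str(sp.bond), sp.mod or "")
                                        for sp in m.sites)))
                    assigned = frozenset((sp.site_name, ws)
                                         for sp, ws in zip(m.sites, assign))
                    key.append((sig, p, assigned))
                key = frozenset(key)
                if key in seen:
                    continue
                seen.add(key)
            results.append((perm, combo))
    return results
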