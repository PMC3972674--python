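"""Minimal polymer fixtures for tests and examples.

A single monomer type ``A(a, a, b~none~mod)`` with two interchangeable
binding sites polymerizes end-to-end.  The plain variant binds any two free
``a`` sites.  The nucleation variant gates polymerization on a modification
at site ``b`` — a monomer may only recruit others once it is itself marked —
and a second, context-dependent rule propagates the mark across a formed
bond, so chains grow exclusively from pre-marked seed monomers.
"""

from __future__ import annotations

from .engine import ForceParams, WorldState
from .geometry import GeometrySpec
from .model import parse_model

__all__ = ["PLAIN_POLYMER_SOURCE", "NUCLEATED_POLYMER_SOURCE", "toy_polymer_fixture"]

PLAIN_POLYMER_SOURCE = """\
begin parameters
  kon 1.0
end parameters
begin molecule types
  A(a,a,b~none~mod)
end molecule types
begin reaction rules
  poly: A(a) + A(a) -> A(a!1).A(a!1) kon
end reaction rules
"""

NUCLEATED_POLYMER_SOURCE = """\
begin parameters
  kon 1.0
  kprop 2.0
end parameters
begin molecule types
  A(a,a,b~none~mod)
end molecule types
begin reaction rules
  poly: A(a,b~mod) + A(a) -> A(a!1,b~mod).A(a!1) kon
  prop: A(a!1,b~mod).A(a!1,b~none) -> A(a!1,b~mod).A(a!1,b~mod) kprop
end reaction rules
"""


def toy_polymer_fixture(n_monomers: int, with_nucleation: bool = False,
                        n_seeds: int = 1, seed: int = 0, box_side: float = 150.0,
                        radius: float = 10.0, force: ForceParams | None = None):
    """Build a toy polymer world: returns ``(model, geometry, world)``.

    ``n_monomers`` monomers are placed at random in a cube of ``box_side``
    Å.  With ``with_nucleation`` the context-gated rule pair replaces plain
    polymerization and the first ``n_seeds`` monomers carry the ``mod`` mark
    on site ``b`` (no seed, no assembly).
    """
    if n_monomers < 1:
        raise ValueError("need at least one monomer")
    source = NUCLEATED_POLYMER_SOURCE if with_nucleation else PLAIN_POLYMER_SOURCE
    model = parse_model(source)
    geometry = {"A": GeometrySpec("A", mass=15.0, radius=radius)}
    half = box_side / 2.0
    force = force or ForceParams(dt=0.5)
    world = WorldState(model, geometry, box=((-half, half),) * 3, seed=seed, force=force)
    for _ in range(n_monomers):
        for _attempt in range(200):
            center = world.rng.uniform(-half, half, size=3)
            import numpy as np

            if world.n_particles:
                d = np.linalg.norm(world.pos - center[None, :], axis=1)
                if float(d.min()) < 1.5 * radius:
                    continue
            world.add_molecule("A", center)
            break
        else:
            raise RuntimeError("box too small for the requested monomer count")
    if with_nucleation:
        for pid in range(min(n_seeds, n_monomers)):
            b_site = [s for s in world.particle_sites(pid) if world.site_name(s) == "b"][0]
            world.set_mod(b_site, "mod")
    return model, geometry, world
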