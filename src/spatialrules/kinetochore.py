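"""The bundled human mitotic kinetochore (HMK) model.

Packaged tables provide the protein geometry (mass-derived sphere radii) and
the interaction map of the inner kinetochore (CCAN), the outer KMN network
and the spindle assembly checkpoint (SAC).  Multi-subunit complexes — the
Mis12, Ndc80, Mad1:Mad2, RZZ and APC complexes, the elongated CenpC/T/Q
proteins, the Ska complex and the microtubule — are structural templates
(flexible bead chains; nucleosomes and microtubules are rigid).

The simulated scene is the mitotic "rosette": a CenpA nucleosome fixed at
the reactor centre with six H3 nucleosomes on a regular hexagon 14 nm away
(fixed positions, free rotation).  All other molecules diffuse in a
centering drag and bind on contact; initially only the seven nucleosomes can
bind anything, so assembly grows outward from the chromatin anchors.

Four variants: an unattached kinetochore (SAC active) and kinetochores
attached to 1, 2 or 3 microtubules (SAC off; with two or more microtubules
all copy numbers are tripled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .engine import ForceParams, SimProtocol, WorldState, run_protocol
from .events import FORMED, BondEvent
from .geometry import GeometrySpec, TemplateDef, TemplateMember, build_template, read_geometry_table
from .model import ModelDef, MoleculeTypeDef, RuleDef, model_from_interactions, read_interaction_table

__all__ = [
    "HMKVariant",
    "VARIANTS",
    "load_hmk_tables",
    "hmk_templates",
    "hmk_copy_numbers",
    "build_variant_world",
    "run_variant",
    "NUCLEOSOME_SPACING_A",
]

NUCLEOSOME_SPACING_A = 140.0  # 14 nm between neighbouring nucleosomes
PLACEMENT_RANGES = ((-400.0, 400.0), (-400.0, 800.0), (-400.0, 400.0))
_APC_CHAIN = ["Apc1", "Apc2", "Apc3", "Apc4", "Apc5", "Apc6", "Apc7", "Apc8",
              "Apc10", "Apc11", "Apc12", "Apc13"]
_LINK_TYPES = _APC_CHAIN + ["Ska1", "Ska2", "Ska3"]
_HISTONE_MASSES = {"H4": 11.4, "H2A": 14.0, "H2B": 13.9}

FREE_SPECIES = [
    "CenpB", "CenpI", "CenpK", "CenpM", "CenpN", "CenpO", "CenpP", "CenpR",
    "CenpS", "CenpU", "CenpW", "CenpX", "Knl1", "Cdc20", "Mad2", "Bub1",
    "BubR1", "Bub3", "Mps1", "Zwint",
]
MOBILE_TEMPLATES = ["cenpC", "cenpT", "cenpQ", "mis12c", "ndc80c", "mad1mad2", "rzz", "apc"]


@dataclass(frozen=True)
class HMKVariant:
    """One of the four simulated kinetochore conditions."""

    name: str
    microtubules: int
    sac_on: bool
    multiplier: int

    def __post_init__(self):
        if self.sac_on != (self.microtubules == 0):
            raise ValueError("the SAC is active exactly when no microtubule is attached")
        if self.multiplier != (3 if self.microtubules >= 2 else 1):
            raise ValueError("copy numbers triple exactly for two or more microtubules")


VARIANTS = {
    "unattached": HMKVariant("unattached", 0, True, 1),
    "attached_1MT": HMKVariant("attached_1MT", 1, False, 1),
    "attached_2MT": HMKVariant("attached_2MT", 2, False, 3),
    "attached_3MT": HMKVariant("attached_3MT", 3, False, 3),
}


def _data_path(name: str):
    return resources.files("spatialrules.data").joinpath(name)


def load_hmk_tables(attached: bool = False, koff: float = 1e-3):
    """Load the packaged geometry and interaction tables.

    Returns ``(geometry, model, interactions)``: one :class:`GeometrySpec`
    per geometry row (printed radius retained where the table prints one),
    and one bind rule per deduplicated interaction pair, SAC-dependent rules
    tagged with the ``SAC`` switch.  With ``attached=True`` the
    microtubule-attachment pairs are appended and, since attachment silences
    the checkpoint, every SAC-gated bond also gets a reverse (unbind) rule
    gated by the ``SAC_OFF`` switch with rate ``koff``.
    """
    with _data_path("hmk_geometry.tsv").open() as fh:
        geometry = read_geometry_table(fh)
    with _data_path("hmk_interactions.tsv").open() as fh:
        inter = read_interaction_table(fh)
    if attached:
        import pandas as pd

        with _data_path("hmk_attachment.tsv").open() as fh:
            inter = pd.concat([inter, read_interaction_table(fh)], ignore_index=True)
    if inter.duplicated(subset=["protein_A", "protein_B"]).any():
        raise ValueError("duplicate interaction rows in packaged table")
    model = model_from_interactions(inter)

    # histone beads and the inert CenpA copy carry no sites; chain complexes
    # without a listed pairwise interaction (APC, Ska) get structural link
    # sites so their internal bonds have endpoints
    types = dict(model.molecule_types)
    for name in list(_HISTONE_MASSES) + ["CenpA2"]:
        types.setdefault(name, MoleculeTypeDef(name, ()))
    for name in _LINK_TYPES:
        if not attached and name.startswith("Ska"):
            continue
        mt = types.get(name, MoleculeTypeDef(name, ()))
        types[name] = MoleculeTypeDef(name, mt.sites + ("lnk1", "lnk2"), dict(mt.mod_states))
    rules = list(model.rules)
    switches = {"SAC": True, "SAC_OFF": False}
    if attached:
        for rule in list(rules):
            if rule.switch == "SAC" and rule.kind == "bind":
                rules.append(
                    RuleDef(rule.name + "_rev", rule.rhs, rule.lhs, koff, "SAC_OFF")
                )
    model = ModelDef(types, rules, switches=switches, parameters=model.parameters)
    return geometry, model, inter


def _rule_sites(inter) -> dict:
    out = {}
    for _, row in inter.iterrows():
        out[(row.protein_A, row.protein_B)] = (row.site_A, row.site_B)
        out[(row.protein_B, row.protein_A)] = (row.site_B, row.site_A)
    return out


def _chain_template(name, members, geometry, rule_sites, zigzag=0.0) -> TemplateDef:
    """A linear bead chain; adjacent beads are bonded through the listed
    interaction sites where one exists, otherwise through structural link
    sites (``lnk1`` toward the previous bead, ``lnk2`` toward the next)."""
    xs = [0.0]
    for a, b in zip(members, members[1:]):
        xs.append(xs[-1] + geometry[a].radius + geometry[b].radius)
    pts = [(x, (zigzag if i % 2 else 0.0), 0.0) for i, x in enumerate(xs)]
    bonds = []
    for i, (a, b) in enumerate(zip(members, members[1:])):
        sa, sb = rule_sites.get((a, b), ("lnk2", "lnk1"))
        bonds.append((i, sa, i + 1, sb))
    return TemplateDef(name, [TemplateMember(t, p) for t, p in zip(members, pts)],
                       internal_bonds=bonds)


def _nucleosome_template(name, core_types, half=6.0) -> TemplateDef:
    """Eight histone-fold beads packed on the vertices of a small cube: a
    rigid, position-fixed nucleosome that is free to rotate in place."""
    verts = [(sx * half, sy * half, sz * half)
             for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    return TemplateDef(
        name,
        [TemplateMember(t, v) for t, v in zip(core_types, verts)],
        rigid=True,
        fixed_position=True,
        free_rotation=True,
    )


def _microtubule_template(geometry, rings=5, per_ring=8, ring_radius=96.0,
                          spacing=64.0) -> TemplateDef:
    """A rigid cylinder of tubulin beads along the template x axis; the
    outer diameter is 25 nm (ring radius + bead radius = 125 Å)."""
    members = []
    for r in range(rings):
        for k in range(per_ring):
            a = 2.0 * math.pi * k / per_ring
            members.append(
                TemplateMember("Tubulin",
                               (r * spacing, ring_radius * math.cos(a), ring_radius * math.sin(a)))
            )
    return TemplateDef("microtubule", members, rigid=True, fixed_position=True,
                       free_rotation=False)


def hmk_templates(geometry, inter, attached: bool = False) -> dict:
    """All structural templates of the model, built against the geometry."""
    import warnings

    rs = _rule_sites(inter)
    tdefs = {
        "nuc_CenpA": _nucleosome_template(
            "nuc_CenpA", ["CenpA", "CenpA2", "H4", "H4", "H2A", "H2A", "H2B", "H2B"]),
        "nuc_H3": _nucleosome_template(
            "nuc_H3", ["H3", "H3", "H4", "H4", "H2A", "H2A", "H2B", "H2B"]),
        "cenpC": _chain_template("cenpC", ["CenpC"], geometry, rs),
        "cenpT": _chain_template("cenpT", ["CenpT"], geometry, rs),
        "cenpQ": _chain_template("cenpQ", ["CenpQ"], geometry, rs),
        "mis12c": _chain_template("mis12c", ["Nsl1", "Dsn1", "Mis12", "Nnf1"], geometry, rs),
        "ndc80c": _chain_template("ndc80c", ["Hec1", "Nuf2", "Spc25", "Spc24"], geometry, rs),
        "mad1mad2": _chain_template("mad1mad2", ["Mad1", "Mad2"], geometry, rs),
        "rzz": _chain_template("rzz", ["Zwilch", "Rod1", "Zw10"], geometry, rs),
        "apc": _chain_template("apc", _APC_CHAIN, geometry, rs),
    }
    if attached:
        tdefs["ska"] = _chain_template(
            "ska", ["Ska3", "Ska2", "Ska1", "Ska1", "Ska2", "Ska3"], geometry, rs,
            zigzag=25.0)  # w-shaped dimer
        tdefs["microtubule"] = _microtubule_template(geometry)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # nucleosome beads overlap by design
        return {name: build_template(td, geometry) for name, td in tdefs.items()}


def hmk_copy_numbers(multiplier: int = 1) -> dict:
    """Effective per-run protein copy numbers for bond-capacity bookkeeping:
    six of everything except CenpA (one) and CenpN (two)."""
    proteins = FREE_SPECIES + ["CenpA", "H3", "CenpC", "CenpT", "CenpQ",
                               "Nsl1", "Dsn1", "Mis12", "Nnf1",
                               "Hec1", "Nuf2", "Spc25", "Spc24",
                               "Mad1", "Zwilch", "Rod1", "Zw10"] + _APC_CHAIN
    out = {p: 6 * multiplier for p in proteins}
    out["CenpA"] = 1
    out["CenpN"] = 2 * multiplier
    return out


def default_force_params() -> ForceParams:
    return ForceParams(
        pair_style="lj",
        epsilon=1.0,
        bond_k=0.2,
        temperature=1.0,
        gamma=1.0,
        dt=1.0,
        drag_center=(0.0, 0.0, 0.0),
        drag_radius=250.0,
        drag_k=0.02,
    )


def build_variant_world(variant, seed: int = 0, n_steps: int = 6_000_000,
                        dump_interval: int = 5_000, force: ForceParams | None = None):
    """Assemble a variant's world and protocol.

    Returns ``(world, protocol, templates)``.  The world holds the fixed
    rosette (CenpA nucleosome at the centre, six H3 nucleosomes on a 14 nm
    hexagon, free rotation), the variant's microtubules, and all mobile
    molecules placed randomly in the standard ranges; the nucleosome beads
    are the growth anchors.  ``world.nucleosome_groups`` lists the seven
    nucleosome particle-id sets for bridge analysis.
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    attached = variant.microtubules > 0
    geometry, model, inter = load_hmk_tables(attached=attached)
    templates = hmk_templates(geometry, inter, attached=attached)
    world = WorldState(model, geometry, box=PLACEMENT_RANGES, seed=seed,
                       force=force or default_force_params(), seeded_growth=True)
    world.react_interval = 20  # encounter-test cadence (steps)
    world.switches["SAC"] = variant.sac_on
    world.switches["SAC_OFF"] = not variant.sac_on

    groups = []
    pids = world.add_template_instance(templates["nuc_CenpA"], (0.0, 0.0, 0.0))
    groups.append(set(pids))
    for k in range(6):
        a = math.radians(60.0 * k)
        center = (NUCLEOSOME_SPACING_A * math.cos(a), 0.0, NUCLEOSOME_SPACING_A * math.sin(a))
        from .engine import _random_rotation

        pids = world.add_template_instance(templates["nuc_H3"], center,
                                           rotation=_random_rotation(world.rng))
        groups.append(set(pids))
    for g in groups:
        for pid in g:
            world.mark_anchor(pid)
    world.nucleosome_groups = groups

    for m in range(variant.microtubules):
        a = 2.0 * math.pi * m / max(1, variant.microtubules)
        offset = 0.0 if variant.microtubules == 1 else 170.0
        center = (offset * math.cos(a), 320.0, offset * math.sin(a))
        rot = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, -1.0]])  # axis -> y
        world.add_template_instance(templates["microtubule"], center, rotation=rot)

    mult = variant.multiplier
    rng_counts = {name: 6 * mult for name in FREE_SPECIES}
    rng_counts["CenpN"] = 2 * mult
    for name in MOBILE_TEMPLATES:
        rng_counts[name] = 6 * mult
    if attached:
        rng_counts["ska"] = 6 * mult
    from .engine import _place_random

    for name, count in rng_counts.items():
        for _ in range(count):
            _place_random(world, name, templates)
    _log_template_rule_bonds(world, model)
    protocol = SimProtocol([("run", int(n_steps))], dump_interval=dump_interval)
    return world, protocol, templates


def _log_template_rule_bonds(world: WorldState, model: ModelDef):
    """Template-internal bonds that realize a listed interaction count as
    realized bonds: log them so bond statistics see them."""
    by_sites = {}
    for rule in model.rules:
        if rule.kind != "bind":
            continue
        (g1, n1, _), (g2, n2, _) = rule.bonds_formed[0]
        t1 = rule.lhs_molecules[g1].type_name
        t2 = rule.lhs_molecules[g2].type_name
        by_sites[frozenset(((t1, n1), (t2, n2)))] = rule.name
    for s1, s2 in world.bond_pairs():
        key = frozenset((
            (world.particle_type_name(world.site_owner(s1)), world.site_name(s1)),
            (world.particle_type_name(world.site_owner(s2)), world.site_name(s2)),
        ))
        rule_name = by_sites.get(key)
        if rule_name is not None:
            world.bond_log.append(
                BondEvent(world.step_count, rule_name,
                          world.site_owner(s1), world.site_slot(s1),
                          world.site_owner(s2), world.site_slot(s2), FORMED)
            )


def run_variant(variant, seed: int = 0, n_steps: int = 6_000_000,
                dump_interval: int = 5_000, force: ForceParams | None = None):
    """Build and simulate one variant; returns ``(world, snapshots, events)``."""
    world, protocol, templates = build_variant_world(
        variant, seed=seed, n_steps=n_steps, dump_interval=dump_interval, force=force)
    snapshots, events = run_protocol(world, protocol, templates)
    return world, snapshots, events
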