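"""Site-graph pattern matching and rule application (graph rewriting).

``match_pattern`` enumerates every injective embedding of a pattern into the
world's site graph; ``apply_rule`` rewrites the world along one embedding.
The world object must expose the small site-graph interface implemented by
:class:`spatialrules.engine.WorldState` (particle types, per-particle site
slots, per-site bond partner and modification label, plus mutators).

Embeddings related by a permutation of identical site names (or of identical
molecule patterns) describe the same rewrite; by default these are
deduplicated so a symmetric dimerization rule does not double-count.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .events import BROKEN, FORMED, BondEvent
from .model import BOUND_ANY, UNBOUND, WILD, ComplexPattern, RuleDef

__all__ = ["Embedding", "StaleEmbeddingError", "match_pattern", "match_lhs", "apply_rule"]


class StaleEmbeddingError(RuntimeError):
    """The world changed since the embedding was computed; nothing was mutated."""


@dataclass(frozen=True)
class Embedding:
    """mol_map[g] = world particle for flattened pattern molecule g;
    site_map[(g, psite_index)] = global world site id."""

    mol_map: tuple
    site_map: dict

    def canonical_key(self, patterns) -> frozenset:
        mols = [m for cp in patterns for m in cp.molecules]
        parts = []
        for g, particle in enumerate(self.mol_map):
            assigned = frozenset(
                (sp.site_name, self.site_map[(g, si)])
                for si, sp in enumerate(mols[g].sites)
            )
            parts.append((_pattern_fingerprint(mols[g]), particle, assigned))
        return frozenset(parts)


def _pattern_fingerprint(mol) -> tuple:
    return (
        mol.type_name,
        tuple(sorted((sp.site_name, str(sp.bond), sp.mod or "") for sp in mol.sites)),
    )


def _site_ok(world, wsite: int, sp) -> bool:
    if world.site_name(wsite) != sp.site_name:
        return False
    partner = world.site_partner(wsite)
    if sp.bond is UNBOUND and partner != -1:
        return False
    if sp.bond is BOUND_ANY and partner == -1:
        return False
    if isinstance(sp.bond, int) and partner == -1:
        return False
    if sp.mod is not None and world.site_mod(wsite) != sp.mod:
        return False
    return True


def _molecule_site_assignments(world, particle: int, mol):
    """Yield dicts psite_index -> world site id, injective per site name."""
    by_name: dict = {}
    for si, sp in enumerate(mol.sites):
        by_name.setdefault(sp.site_name, []).append(si)
    world_slots: dict = {}
    for ws in world.particle_sites(particle):
        world_slots.setdefault(world.site_name(ws), []).append(ws)
    name_choices = []
    for name, psites in by_name.items():
        slots = world_slots.get(name, [])
        if len(slots) < len(psites):
            return
        ok_perms = []
        for perm in itertools.permutations(slots, len(psites)):
            if all(_site_ok(world, w, mol.sites[p]) for p, w in zip(psites, perm)):
                ok_perms.append(dict(zip(psites, perm)))
        if not ok_perms:
            return
        name_choices.append(ok_perms)
    for combo in itertools.product(*name_choices):
        merged: dict = {}
        for d in combo:
            merged.update(d)
        yield merged


def _bond_labels_consistent(world, patterns, mol_map, site_map) -> bool:
    mols_offsets = []
    off = 0
    for cp in patterns:
        mols_offsets.append(off)
        off += len(cp.molecules)
    for ci, cp in enumerate(patterns):
        base = mols_offsets[ci]
        ends = cp.bond_ends()
        for label, ((m1, s1), (m2, s2)) in ((k, tuple(v)) for k, v in ends.items()):
            w1 = site_map[(base + m1, s1)]
            w2 = site_map[(base + m2, s2)]
            if world.site_partner(w1) != w2 or world.site_partner(w2) != w1:
                return False
    return True


def _match(world, patterns, anchor=None, dedup=True, max_embeddings=None):
    mols = [m for cp in patterns for m in cp.molecules]
    n = len(mols)
    results: list[Embedding] = []
    seen: set = set()
    candidates_all = list(range(world.n_particles))

    def backtrack(g, mol_map, site_map, used):
        if max_embeddings is not None and len(results) >= max_embeddings:
            return
        if g == n:
            if not _bond_labels_consistent(world, patterns, mol_map, site_map):
                return
            emb = Embedding(tuple(mol_map), dict(site_map))
            if anchor is not None:
                a_particle = anchor[0] if isinstance(anchor, tuple) else anchor
                if a_particle not in emb.mol_map:
                    return
                if isinstance(anchor, tuple) and anchor[1] not in emb.site_map.values():
                    return
            if dedup:
                key = emb.canonical_key(patterns)
                if key in seen:
                    return
                seen.add(key)
            results.append(emb)
            return
        mol = mols[g]
        for particle in candidates_all:
            if particle in used:
                continue
            if world.particle_type(particle).name != mol.type_name:
                continue
            for assignment in _molecule_site_assignments(world, particle, mol):
                mol_map.append(particle)
                used.add(particle)
                for psi, ws in assignment.items():
                    site_map[(g, psi)] = ws
                backtrack(g + 1, mol_map, site_map, used)
                for psi in assignment:
                    del site_map[(g, psi)]
                used.discard(particle)
                mol_map.pop()

    backtrack(0, [], {}, set())
    return results


def match_pattern(pattern: ComplexPattern, world, anchor=None, dedup: bool = True):
    """All injective embeddings of one complex pattern into the world.

    ``anchor`` restricts the result to embeddings covering a given particle
    (or ``(particle, world site id)`` pair).  Returns a list of
    :class:`Embedding`; empty when nothing matches.
    """
    return _match(world, (pattern,), anchor=anchor, dedup=dedup)


def match_lhs(rule: RuleDef, world, anchor=None, dedup: bool = True, max_embeddings=None):
    """Embeddings of a rule's full left-hand side (all its complexes jointly)."""
    return _match(world, rule.lhs, anchor=anchor, dedup=dedup, max_embeddings=max_embeddings)


def _lhs_site_index(rule: RuleDef, g: int, name: str, occ: int) -> int:
    mol = rule.lhs_molecules[g]
    count = 0
    for si, sp in enumerate(mol.sites):
        if sp.site_name == name:
            if count == occ:
                return si
            count += 1
    raise KeyError((g, name, occ))


def _validate_embedding(world, rule: RuleDef, emb: Embedding) -> bool:
    mols = rule.lhs_molecules
    for (g, psi), ws in emb.site_map.items():
        if world.site_owner(ws) != emb.mol_map[g]:
            return False
        if not _site_ok(world, ws, mols[g].sites[psi]):
            return False
    return _bond_labels_consistent(world, rule.lhs, emb.mol_map, emb.site_map)


def apply_rule(world, rule: RuleDef, emb: Embedding, step: int = 0):
    """Rewrite the world along ``emb`` as ``rule`` prescribes.

    Bonds are formed/broken and modification labels rewritten exactly as the
    two rule sides differ; every other site is untouched.  Returns the list of
    emitted :class:`BondEvent`.  If the embedding no longer matches the
    current world (a site changed since matching), raises
    :class:`StaleEmbeddingError` and leaves the world unmodified.
    """
    if not _validate_embedding(world, rule, emb):
        raise StaleEmbeddingError(f"embedding for rule {rule.name!r} is stale")
    events = []

    def wsite(key):
        g, name, occ = key
        return emb.site_map[(g, _lhs_site_index(rule, g, name, occ))]

    for k1, k2 in rule.bonds_formed:
        w1, w2 = wsite(k1), wsite(k2)
        if world.site_partner(w1) != -1 or world.site_partner(w2) != -1:
            raise StaleEmbeddingError("bond target site no longer free")
    for k1, k2 in rule.bonds_formed:
        w1, w2 = wsite(k1), wsite(k2)
        world.form_bond(w1, w2)
        events.append(
            BondEvent(step, rule.name, world.site_owner(w1), world.site_slot(w1),
                      world.site_owner(w2), world.site_slot(w2), FORMED)
        )
    for k1, k2 in rule.bonds_broken:
        w1, w2 = wsite(k1), wsite(k2)
        world.break_bond(w1)
        events.append(
            BondEvent(step, rule.name, world.site_owner(w1), world.site_slot(w1),
                      world.site_owner(w2), world.site_slot(w2), BROKEN)
        )
    for key, new_label in rule.mod_changes:
        world.set_mod(wsite(key), new_label)
    return events
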