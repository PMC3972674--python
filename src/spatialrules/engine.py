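"""Coarse-grained Brownian-dynamics engine with rule firing.

Particles are spheres moving by overdamped Langevin dynamics in a reflective
box: deterministic forces (excluded-volume pair repulsion, harmonic bonds,
optional harmonic angles, an optional centering drag) plus Gaussian noise
with variance ``2 kT dt / gamma`` per axis.  Reduced units: energies in kT,
lengths in Å, friction ``gamma`` = 1, so the free diffusion coefficient is
``D = kT / gamma`` Å² per unit time.

Reactive sites fire enabled reaction rules: a bimolecular bind rule fires
with a per-encounter probability when two matching free sites come within
the sum of their reaches (plus a small slack); unimolecular rules fire with
probability ``1 - exp(-k dt)`` per matched embedding.  Rigid templates move
and rotate as rigid bodies; templates anchored at a fixed position may still
rotate freely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import matching
from .events import BROKEN, FORMED, BondEvent
from .geometry import BuiltTemplate, GeometrySpec
from .matching import StaleEmbeddingError
from .model import ModelDef

__all__ = [
    "ForceParams",
    "SimProtocol",
    "WorldState",
    "init_world",
    "step_dynamics",
    "fire_reactions",
    "run_protocol",
]

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@dataclass
class ForceParams:
    """Force-field and integrator parameters (reduced units, lengths in Å).

    ``pair_style`` is ``"lj"`` (Lennard-Jones truncated at its minimum, i.e.
    purely repulsive excluded volume, with ``sigma`` defaulting to the sum of
    the two radii) or ``"none"``.  Bonds are harmonic with rest length equal
    to the sum of the two site reaches.  ``drag_*`` define the optional
    centering drag: a harmonic pull applied outside a sphere of
    ``drag_radius`` around ``drag_center``.
    """

    pair_style: str = "lj"
    epsilon: float = 1.0
    bond_k: float = 0.5
    angle_k: float = 0.0
    temperature: float = 1.0
    gamma: float = 1.0
    dt: float = 0.5
    drag_center: tuple | None = None
    drag_radius: float = 0.0
    drag_k: float = 0.0
    force_cap: float = 4.0  # per-pair force cap, kT/Å
    max_step: float = 10.0  # per-axis displacement cap per step, Å

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("bond_k", "angle_k", "epsilon", "gamma", "drag_k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def mobility(self) -> float:
        return self.dt / self.gamma

    @property
    def noise_sigma(self) -> float:
        return math.sqrt(2.0 * self.temperature * self.dt / self.gamma)


@dataclass
class SimProtocol:
    """An ordered list of phases plus the snapshot interval.

    Phases: ``("run", n_steps)``, ``("add", count, name)`` (molecule type or
    template), ``("switch", tag, on)``, ``("force", attr, value)``.
    """

    phases: list = field(default_factory=list)
    dump_interval: int = 5000

    def __post_init__(self):
        for ph in self.phases:
            if ph[0] == "run" and ph[1] < 0:
                raise ValueError("run phase needs a non-negative step count")
            if ph[0] == "add" and ph[1] <= 0:
                raise ValueError("add phase needs a positive copy count")


class _DSU:
    """Union-find over particles, tracking which complexes touch an anchor."""

    def __init__(self):
        self.parent: list[int] = []
        self.anchored: list[bool] = []

    def add(self, anchored: bool = False):
        self.parent.append(len(self.parent))
        self.anchored.append(anchored)

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        anch = self.anchored[ra] or self.anchored[rb]
        self.parent[ra] = rb
        self.anchored[rb] = anch

    def is_anchored(self, i: int) -> bool:
        return self.anchored[self.find(i)]


@dataclass
class _RigidGroup:
    members: np.ndarray  # particle ids
    fixed: bool
    free_rotation: bool
    centroid: np.ndarray
    offsets: np.ndarray  # world-frame member offsets from centroid


class WorldState:
    """All particle instances, their site graph, and the simulation state."""

    def __init__(self, model: ModelDef, geometry: dict, box, seed: int = 0,
                 force: ForceParams | None = None, seeded_growth: bool = False):
        self.model = model
        self.geometry = geometry
        self.box = np.asarray(box, dtype=float).reshape(3, 2)
        if np.any(self.box[:, 1] <= self.box[:, 0]):
            raise ValueError("box extents must have hi > lo on every axis")
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)
        self.force = force or ForceParams()
        self.switches = dict(model.switches)
        self.seeded_growth = seeded_growth
        self.step_count = 0
        self.bond_log: list[BondEvent] = []

        self.type_names = list(model.molecule_types)
        self._type_index = {n: i for i, n in enumerate(self.type_names)}
        self.mod_labels = model.mod_labels
        self._mod_index = {m: i for i, m in enumerate(self.mod_labels)}

        # particle arrays
        self.pos = np.empty((0, 3))
        self.type_id = np.empty(0, dtype=np.int32)
        self.radius = np.empty(0)
        self.group_id = np.empty(0, dtype=np.int32)
        self.groups: list[_RigidGroup] = []
        # flattened site arrays
        self._site_ptr = np.zeros(1, dtype=np.int64)
        self._site_owner = np.empty(0, dtype=np.int32)
        self._site_slot = np.empty(0, dtype=np.int32)
        self.site_bond = np.empty(0, dtype=np.int64)
        self.site_mod_id = np.empty(0, dtype=np.int16)
        self.site_length = np.empty(0)
        self._bond_r0: dict = {}

        self._dsu = _DSU()
        self._anchor_flags: list[bool] = []
        self._dirty = True  # force/bond caches stale
        self._rule_tables_built = False
        self.react_interval = 10
        self.bind_slack = 0.1
        self.cone_half_angle = 45.0

    # -- site-graph interface used by spatialrules.matching ---------------

    @property
    def n_particles(self) -> int:
        return self.pos.shape[0]

    def particle_type(self, i: int):
        return self.model.molecule_types[self.type_names[self.type_id[i]]]

    def particle_type_name(self, i: int) -> str:
        return self.type_names[self.type_id[i]]

    def particle_sites(self, i: int):
        return range(int(self._site_ptr[i]), int(self._site_ptr[i + 1]))

    def site_owner(self, s: int) -> int:
        return int(self._site_owner[s])

    def site_slot(self, s: int) -> int:
        return int(self._site_slot[s])

    def site_name(self, s: int) -> str:
        return self.particle_type(self._site_owner[s]).sites[self._site_slot[s]]

    def site_partner(self, s: int) -> int:
        return int(self.site_bond[s])

    def site_mod(self, s: int) -> str | None:
        m = int(self.site_mod_id[s])
        return None if m < 0 else self.mod_labels[m]

    def set_mod(self, s: int, label: str):
        self.site_mod_id[s] = self._mod_index[label]

    def form_bond(self, s1: int, s2: int, rest_length: float | None = None):
        if self.site_bond[s1] != -1 or self.site_bond[s2] != -1:
            raise ValueError("site already bound")
        self.site_bond[s1] = s2
        self.site_bond[s2] = s1
        if rest_length is None:
            rest_length = float(self.site_length[s1] + self.site_length[s2])
        self._bond_r0[(min(s1, s2), max(s1, s2))] = rest_length
        self._dsu.union(self.site_owner(s1), self.site_owner(s2))
        self._dirty = True
        self._bonds_version += 1

    def break_bond(self, s1: int):
        s2 = int(self.site_bond[s1])
        if s2 == -1:
            raise ValueError("site is not bound")
        self.site_bond[s1] = -1
        self.site_bond[s2] = -1
        self._bond_r0.pop((min(s1, s2), max(s1, s2)), None)
        # anchored-complex bookkeeping is conservative: rebuild lazily
        self._dsu = self._rebuild_dsu()
        self._dirty = True
        self._bonds_version += 1

    def bond_pairs(self) -> list:
        """Current bonds as sorted (site1, site2) pairs, site1 < site2."""
        s1 = np.nonzero(self.site_bond >= 0)[0]
        return [(int(a), int(self.site_bond[a])) for a in s1 if a < self.site_bond[a]]

    def bond_count(self) -> int:
        return int(np.count_nonzero(self.site_bond >= 0) // 2)

    # -- construction ------------------------------------------------------

    def _intern_type(self, name: str) -> int:
        if name not in self._type_index:
            raise KeyError(f"unknown molecule type {name!r}")
        return self._type_index[name]

    def add_molecule(self, type_name: str, position, anchored: bool = False) -> int:
        tid = self._intern_type(type_name)
        mt = self.model.molecule_types[type_name]
        spec: GeometrySpec = self.geometry[type_name]
        pid = self.n_particles
        self.pos = np.vstack([self.pos, np.asarray(position, dtype=float).reshape(1, 3)])
        self.type_id = np.append(self.type_id, np.int32(tid))
        self.radius = np.append(self.radius, spec.radius)
        self.group_id = np.append(self.group_id, np.int32(-1))
        nsites = len(mt.sites)
        self._site_ptr = np.append(self._site_ptr, self._site_ptr[-1] + nsites)
        self._site_owner = np.append(self._site_owner, np.full(nsites, pid, dtype=np.int32))
        self._site_slot = np.append(self._site_slot, np.arange(nsites, dtype=np.int32))
        self.site_bond = np.append(self.site_bond, np.full(nsites, -1, dtype=np.int64))
        mods = [
            self._mod_index[mt.mod_states[s][0]] if mt.mod_states.get(s) else -1
            for s in mt.sites
        ]
        self.site_mod_id = np.append(self.site_mod_id, np.asarray(mods, dtype=np.int16))
        self.site_length = np.append(
            self.site_length, [spec.site_length(s) for s in mt.sites]
        )
        self._anchor_flags.append(bool(anchored))
        self._dsu.add(bool(anchored))
        self._dirty = True
        return pid

    def add_template_instance(self, built: BuiltTemplate, center, rotation=None,
                              anchored: bool = False) -> list:
        center = np.asarray(center, dtype=float)
        offs = built.positions - built.positions.mean(axis=0)
        if rotation is not None:
            offs = offs @ np.asarray(rotation).T
        pids = [
            self.add_molecule(tn, center + off, anchored=anchored)
            for tn, off in zip(built.type_names, offs)
        ]
        for i, si, j, sj, rest in built.internal_bonds:
            s1 = self._site_of(pids[i], si)
            s2 = self._site_of(pids[j], sj)
            self.form_bond(s1, s2, rest_length=rest)
        if built.rigid or built.fixed_position:
            members = np.asarray(pids, dtype=np.int64)
            grp = _RigidGroup(
                members,
                built.fixed_position,
                built.free_rotation or not built.fixed_position,
                self.pos[members].mean(axis=0).copy(),
                self.pos[members] - self.pos[members].mean(axis=0),
            )
            gid = len(self.groups)
            self.groups.append(grp)
            self.group_id[members] = gid
        return pids

    def _site_of(self, pid: int, site_name: str, free_only: bool = True) -> int:
        for s in self.particle_sites(pid):
            if self.site_name(s) == site_name and (not free_only or self.site_bond[s] == -1):
                return s
        raise KeyError(f"particle {pid} has no free site {site_name!r}")

    def orientation(self, i: int) -> np.ndarray | None:
        return None  # free particles carry no orientation; groups move sites rigidly

    # -- internal caches ---------------------------------------------------

    def _rebuild_dsu(self) -> _DSU:
        dsu = _DSU()
        for i in range(self.n_particles):
            dsu.add(self._anchor_flags[i])
        for s1, s2 in self.bond_pairs():
            dsu.union(self.site_owner(s1), self.site_owner(s2))
        return dsu

    def mark_anchor(self, pid: int):
        self._anchor_flags[pid] = True
        self._dsu.anchored[self._dsu.find(pid)] = True

    def complex_anchored(self, pid: int) -> bool:
        return self._dsu.is_anchored(pid)

    def _refresh_force_arrays(self):
        pairs = self.bond_pairs()
        bi = np.array([self.site_owner(a) for a, _ in pairs], dtype=np.int64)
        bj = np.array([self.site_owner(b) for _, b in pairs], dtype=np.int64)
        br0 = np.array([self._bond_r0[p] for p in pairs], dtype=float)
        self._bond_arrays = (bi, bj, br0)
        self._free_idx = np.nonzero(self.group_id < 0)[0].astype(np.int64)
        self._pair_cache = None
        # rigid-group flat arrays
        G = len(self.groups)
        gm = np.concatenate([g.members for g in self.groups]) if G else np.empty(0, dtype=np.int64)
        gstart = np.zeros(G + 1, dtype=np.int64)
        for gi, g in enumerate(self.groups):
            gstart[gi + 1] = gstart[gi] + len(g.members)
        self._grp = (
            gm,
            gstart,
            np.array([g.fixed for g in self.groups], dtype=np.uint8),
            np.array([g.free_rotation for g in self.groups], dtype=np.uint8),
        )
        f = self.force
        ginvgrot = np.empty(G)
        gsig_t = np.empty(G)
        gsig_r = np.empty(G)
        for gi, g in enumerate(self.groups):
            grot = f.gamma * max(1e-9, float(np.sum(g.offsets**2)))
            ginvgrot[gi] = f.dt / grot
            gsig_t[gi] = f.noise_sigma / math.sqrt(len(g.members))
            gsig_r[gi] = math.sqrt(2.0 * f.temperature * f.dt / grot)
        self._grp_dyn = (ginvgrot, gsig_t, gsig_r)
        self._gcen = (np.stack([g.centroid for g in self.groups]) if G
                      else np.empty((0, 3)))
        self._goff = (np.concatenate([g.offsets for g in self.groups], axis=0)
                      if G else np.empty((0, 3)))
        self._Fbuf = np.zeros_like(self.pos)
        self._angle_triplets = self._build_angle_triplets() if self.force.angle_k > 0 else (
            np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64), np.empty(0))
        self._dirty = False

    def _build_angle_triplets(self):
        ti, tj, tk, th0 = [], [], [], []
        for j in range(self.n_particles):
            spec = self.geometry[self.particle_type_name(j)]
            bound = [s for s in self.particle_sites(j) if self.site_bond[s] != -1]
            for a in range(len(bound)):
                for b in range(a + 1, len(bound)):
                    pa = spec.site_placements.get(self.site_name(bound[a]))
                    pb = spec.site_placements.get(self.site_name(bound[b]))
                    if pa is None or pb is None:
                        continue
                    va, vb = pa.offset(), pb.offset()
                    cosang = float(np.dot(va, vb) / (np.linalg.norm(va) * np.linalg.norm(vb)))
                    ti.append(self.site_owner(int(self.site_bond[bound[a]])))
                    tj.append(j)
                    tk.append(self.site_owner(int(self.site_bond[bound[b]])))
                    th0.append(math.acos(max(-1.0, min(1.0, cosang))))
        return (np.array(ti, dtype=np.int64), np.array(tj, dtype=np.int64),
                np.array(tk, dtype=np.int64), np.array(th0, dtype=float))

    # -- rule dispatch tables ---------------------------------------------

    def _build_rule_tables(self):
        """Classify rules into the fast bimolecular-bind path, the fast
        simple-unbind path, and the generic (pattern-matched) path."""
        self._bind_lookup: dict = {}
        self._uni_rules: list = []
        self._context_bind: list = []
        self._max_reach = 0.0
        for ridx, rule in enumerate(self.model.rules):
            if rule.kind == "bind" and len(rule.lhs) == 2 and all(
                len(cp.molecules) == 1 for cp in rule.lhs
            ):
                (k1, k2) = rule.bonds_formed[0]
                g1, n1, _ = k1
                g2, n2, _ = k2
                m1 = rule.lhs_molecules[g1]
                m2 = rule.lhs_molecules[g2]
                t1, t2 = m1.type_name, m2.type_name
                slots1 = self.model.molecule_types[t1].site_slots(n1)
                slots2 = self.model.molecule_types[t2].site_slots(n2)
                simple = all(
                    len(m.sites) == 1 and m.sites[0].mod is None for m in (m1, m2)
                )
                for sl1 in slots1:
                    for sl2 in slots2:
                        self._bind_lookup.setdefault((t1, sl1, t2, sl2), []).append(
                            (ridx, simple)
                        )
                        if (t1, sl1) != (t2, sl2):
                            self._bind_lookup.setdefault((t2, sl2, t1, sl1), []).append(
                                (ridx, simple)
                            )
                reach = (
                    self.geometry[t1].site_length(n1) + self.geometry[t2].site_length(n2)
                )
                self._max_reach = max(self._max_reach, reach * (1.0 + self.bind_slack))
            else:
                self._uni_rules.append(ridx)
        self._reactive_slots = {
            (t, slot) for (t, slot, _, _) in self._bind_lookup
        }
        # static per-site reactivity mask and per-particle maximum reach
        nsites = len(self.site_bond)
        self._site_reactive = np.zeros(nsites, dtype=bool)
        for s in range(nsites):
            key = (self.particle_type_name(int(self._site_owner[s])), int(self._site_slot[s]))
            self._site_reactive[s] = key in self._reactive_slots
        self._particle_reach = np.zeros(self.n_particles)
        for s in np.nonzero(self._site_reactive)[0]:
            o = int(self._site_owner[s])
            self._particle_reach[o] = max(self._particle_reach[o], float(self.site_length[s]))
        self._site_keys = [
            (self.particle_type_name(int(self._site_owner[s])), int(self._site_slot[s]))
            for s in range(nsites)
        ]
        self._site_has_angle = np.array([
            self.geometry[tn].site_placements.get(
                self.model.molecule_types[tn].sites[slot]) is not None
            for tn, slot in self._site_keys
        ], dtype=bool) if nsites else np.zeros(0, dtype=bool)
        ntypes = len(self.type_names)
        compat = np.zeros((ntypes, ntypes), dtype=bool)
        self._type_pair_slots: dict = {}
        for (t1, sl1, t2, sl2), entries in self._bind_lookup.items():
            i1, i2 = self._type_index[t1], self._type_index[t2]
            compat[i1, i2] = compat[i2, i1] = True
            self._type_pair_slots.setdefault((i1, i2), []).append((sl1, sl2, entries))
        self._type_compat = compat
        self._rule_tables_sites = nsites
        self._rule_tables_built = True

    def rule_enabled(self, rule) -> bool:
        return rule.switch is None or self.switches.get(rule.switch, True)

    # -- dynamics ----------------------------------------------------------

    def advance(self, n_steps: int):
        """Integrate ``n_steps`` Brownian-dynamics steps (no reactions)."""
        if n_steps <= 0:
            return
        if self._dirty:
            self._refresh_force_arrays()
        f = self.force
        bi, bj, br0 = self._bond_arrays
        gm, gstart, gfixed, grotfree = self._grp
        ginvgrot, gsig_t, gsig_r = self._grp_dyn
        G = len(self.groups)
        gcen, goff, Fbuf = self._gcen, self._goff, self._Fbuf
        drag_c = np.asarray(f.drag_center, dtype=float) if f.drag_center is not None else np.zeros(3)
        drag_k = f.drag_k if f.drag_center is not None else 0.0
        ti, tj, tk, th0 = self._angle_triplets
        max_chunk = 200
        done = 0
        while done < n_steps:
            chunk = min(max_chunk, n_steps - done)
            if (self._pair_cache is None
                    or 2.0 * math.sqrt(2.0 * (self._steps_since_pairs + chunk))
                    * f.noise_sigma > self._pair_skin):
                self._pair_cache = self._pair_list()
                self._steps_since_pairs = 0
            noise = self.rng.standard_normal((chunk, len(self._free_idx), 3)) * f.noise_sigma
            gnoise = (self.rng.standard_normal((chunk, G, 3)) * gsig_t[None, :, None]
                      if G else np.empty((chunk, 0, 3)))
            grnoise = (self.rng.standard_normal((chunk, G, 3)) * gsig_r[None, :, None]
                       if G else np.empty((chunk, 0, 3)))
            pair_i, pair_j, pair_sig = self._pair_cache
            maxdisp = _bd_chunk(
                self.pos, Fbuf, self._free_idx, noise,
                bi, bj, br0, f.bond_k,
                pair_i, pair_j, pair_sig, f.epsilon, f.force_cap,
                ti, tj, tk, th0, f.angle_k,
                gm, gstart, gfixed, grotfree, gcen, goff, ginvgrot,
                gnoise, grnoise,
                self.box[:, 0].copy(), self.box[:, 1].copy(),
                f.mobility, drag_c, f.drag_radius, drag_k, f.max_step,
            )
            if maxdisp > 0.5 * float(np.min(self.box[:, 1] - self.box[:, 0])):
                raise RuntimeError(
                    f"integration unstable: single-step displacement {maxdisp:.1f} Å "
                    "exceeds half the smallest box extent; reduce dt or stiffnesses"
                )
            done += chunk
            self.step_count += chunk
            self._steps_since_pairs += chunk
        for gi, g in enumerate(self.groups):
            g.centroid = gcen[gi]
            g.offsets = goff[gstart[gi]:gstart[gi + 1]]

    _pair_skin = 18.0  # Å of margin on the cached excluded-volume pair list
    _steps_since_pairs = 0
    _pair_cache = None
    _bonds_version = 0
    _reactive_cache = None

    def _pair_list(self):
        """Excluded-volume pair list with a skin margin (bonded pairs and
        same-rigid-group pairs excluded); refreshed when accumulated random
        motion could invalidate it."""
        empty = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), np.empty(0))
        if self.force.pair_style == "none" or self.n_particles < 2:
            return empty
        cutoff = 2.0 * float(self.radius.max()) * 1.13 + self._pair_skin
        tree = cKDTree(self.pos)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs) == 0:
            return empty
        n = self.n_particles
        sig = self.radius[pairs[:, 0]] + self.radius[pairs[:, 1]]
        dist = np.linalg.norm(self.pos[pairs[:, 0]] - self.pos[pairs[:, 1]], axis=1)
        keep = dist < sig * 1.13 + self._pair_skin
        same_group = (self.group_id[pairs[:, 0]] >= 0) & (
            self.group_id[pairs[:, 0]] == self.group_id[pairs[:, 1]]
        )
        keep &= ~same_group
        bi, bj, _ = self._bond_arrays
        if len(bi):
            bond_keys = np.minimum(bi, bj) * n + np.maximum(bi, bj)
            pair_keys = (np.minimum(pairs[:, 0], pairs[:, 1]) * n
                         + np.maximum(pairs[:, 0], pairs[:, 1]))
            keep &= ~np.isin(pair_keys, bond_keys)
        pairs = pairs[keep]
        return pairs[:, 0].astype(np.int64), pairs[:, 1].astype(np.int64), sig[keep]

    # -- reactions ---------------------------------------------------------

    def fire_reactions(self) -> list:
        """One reaction sweep; returns (and logs) the emitted bond events."""
        if not self._rule_tables_built:
            self._build_rule_tables()
        events: list[BondEvent] = []
        events.extend(self._fire_bimolecular())
        events.extend(self._fire_unimolecular())
        self.bond_log.extend(events)
        return events

    def _fire_bimolecular(self) -> list:
        if not self._bind_lookup or self._max_reach <= 0:
            return []
        if len(self.site_bond) != self._rule_tables_sites:
            self._build_rule_tables()  # particles were added since
        if (self._reactive_cache is None
                or self._reactive_cache[0] != self._bonds_version):
            reactive = np.nonzero((self.site_bond < 0) & self._site_reactive)[0]
            owners = self._site_owner[reactive]
            slot_site = {
                (int(o), int(self._site_slot[s])): int(s)
                for s, o in zip(reactive, owners)
            }
            self._reactive_cache = (
                self._bonds_version, reactive, np.unique(owners), slot_site
            )
        _, reactive, uniq_owner, slot_site = self._reactive_cache
        if len(reactive) < 2:
            return []
        tree = cKDTree(self.pos[uniq_owner])
        cand = tree.query_pairs(self._max_reach, output_type="ndarray")
        if len(cand) == 0:
            return []
        pa_arr = uniq_owner[cand[:, 0]]
        pb_arr = uniq_owner[cand[:, 1]]
        dists = np.linalg.norm(self.pos[pa_arr] - self.pos[pb_arr], axis=1)
        within = dists <= (
            (self._particle_reach[pa_arr] + self._particle_reach[pb_arr])
            * (1.0 + self.bind_slack)
        )
        within &= self._type_compat[self.type_id[pa_arr], self.type_id[pb_arr]]
        if self.seeded_growth and np.any(within):
            anchored = np.fromiter(
                (self._dsu.is_anchored(int(p)) for p in uniq_owner), dtype=bool,
                count=len(uniq_owner),
            )
            lookup = {int(p): a for p, a in zip(uniq_owner, anchored)}
            within &= np.fromiter(
                (lookup[int(a)] or lookup[int(b)] for a, b in zip(pa_arr, pb_arr)),
                dtype=bool, count=len(pa_arr),
            )
        if not np.any(within):
            return []
        pa_arr, pb_arr, dists = pa_arr[within], pb_arr[within], dists[within]
        order = self.rng.permutation(len(pa_arr))
        events: list[BondEvent] = []
        used: set = set()
        context_cache: dict = {}
        tid = self.type_id
        for u in order:
            pa = int(pa_arr[u])
            pb = int(pb_arr[u])
            dist = float(dists[u])
            combos = self._type_pair_slots.get((int(tid[pa]), int(tid[pb])))
            if not combos:
                continue
            for sl_a, sl_b, entries in combos:
                sa = slot_site.get((pa, sl_a))
                if sa is None or sa in used or self.site_bond[sa] != -1:
                    continue
                sb = slot_site.get((pb, sl_b))
                if sb is None or sb in used or sb == sa or self.site_bond[sb] != -1:
                    continue
                ev = self._try_bind(sa, sb, dist, context_cache, entries)
                if ev is not None:
                    events.append(ev)
                    used.add(sa)
                    used.add(sb)
                    break  # at most one new bond per particle pair per sweep
        return events

    def _try_bind(self, sa: int, sb: int, dist: float, context_cache: dict,
                  entries=None):
        if entries is None:
            entries = self._bind_lookup.get(self._site_keys[sa] + self._site_keys[sb])
            if not entries:
                return None
        for ridx, simple in entries:
            rule = self.model.rules[ridx]
            if not self.rule_enabled(rule):
                continue
            reach = (self.site_length[sa] + self.site_length[sb]) * (1.0 + self.bind_slack)
            if dist > reach:
                continue
            if (self._site_has_angle[sa] and not self._angular_ok(sa, sb)) or (
                self._site_has_angle[sb] and not self._angular_ok(sb, sa)
            ):
                continue
            if self.seeded_growth and not (
                self.complex_anchored(self.site_owner(sa))
                or self.complex_anchored(self.site_owner(sb))
            ):
                continue
            if not simple and not self._context_ok(rule, ridx, sa, sb, context_cache):
                continue
            if rule.rate < 1.0 and self.rng.random() >= rule.rate:
                continue
            self.form_bond(sa, sb)
            return BondEvent(
                self.step_count, rule.name,
                self.site_owner(sa), self.site_slot(sa),
                self.site_owner(sb), self.site_slot(sb), FORMED,
            )
        return None

    def _context_ok(self, rule, ridx, sa, sb, cache) -> bool:
        """A non-simple bind rule carries extra pattern context (modification
        states, bound neighbours); verify the candidate site pair sits inside
        some full LHS embedding.  Embeddings are computed once per sweep."""
        if ridx not in cache:
            embs = matching.match_lhs(rule, self, dedup=True)
            cache[ridx] = {
                frozenset(self._emb_bind_sites(rule, emb)) for emb in embs
            }
        return frozenset((sa, sb)) in cache[ridx]

    def _emb_bind_sites(self, rule, emb):
        (k1, k2) = rule.bonds_formed[0]
        s1 = emb.site_map[(k1[0], matching._lhs_site_index(rule, *k1))]
        s2 = emb.site_map[(k2[0], matching._lhs_site_index(rule, *k2))]
        return (s1, s2)

    def _angular_ok(self, s_from: int, s_to: int) -> bool:
        owner = self.site_owner(s_from)
        spec = self.geometry[self.particle_type_name(owner)]
        pl = spec.site_placements.get(self.site_name(s_from))
        if pl is None:
            return True  # isotropic site: whole surface reactive
        # site axis in the declared body frame; free spheres carry no
        # rotational state, so the declared frame is the body frame
        axis = pl.offset()
        direction = self.pos[self.site_owner(s_to)] - self.pos[owner]
        nrm = np.linalg.norm(axis) * np.linalg.norm(direction)
        if nrm < 1e-12:
            return True
        cosang = float(np.dot(axis, direction) / nrm)
        return math.degrees(math.acos(max(-1.0, min(1.0, cosang)))) <= self.cone_half_angle

    def _fire_unimolecular(self) -> list:
        events: list[BondEvent] = []
        dt_eff = self.force.dt * self.react_interval
        for ridx in self._uni_rules:
            rule = self.model.rules[ridx]
            if not self.rule_enabled(rule):
                continue
            p = 1.0 - math.exp(-rule.rate * dt_eff)
            if p <= 0:
                continue
            if rule.kind == "unbind" and self._is_simple_unbind(rule):
                events.extend(self._fire_simple_unbind(rule, p))
                continue
            for emb in matching.match_lhs(rule, self, dedup=True):
                if self.rng.random() < p:
                    try:
                        events.extend(matching.apply_rule(self, rule, emb, self.step_count))
                    except StaleEmbeddingError:
                        continue
        return events

    @staticmethod
    def _is_simple_unbind(rule) -> bool:
        return (
            len(rule.lhs) == 1
            and len(rule.lhs[0].molecules) == 2
            and all(
                len(m.sites) == 1 and m.sites[0].mod is None
                for m in rule.lhs[0].molecules
            )
        )

    def _fire_simple_unbind(self, rule, p: float) -> list:
        m1, m2 = rule.lhs[0].molecules
        events = []
        for s1, s2 in list(self.bond_pairs()):
            o1, o2 = self.site_owner(s1), self.site_owner(s2)
            match = (
                self.particle_type_name(o1) == m1.type_name
                and self.site_name(s1) == m1.sites[0].site_name
                and self.particle_type_name(o2) == m2.type_name
                and self.site_name(s2) == m2.sites[0].site_name
            ) or (
                self.particle_type_name(o2) == m1.type_name
                and self.site_name(s2) == m1.sites[0].site_name
                and self.particle_type_name(o1) == m2.type_name
                and self.site_name(s1) == m2.sites[0].site_name
            )
            if match and self.rng.random() < p:
                self.break_bond(s1)
                events.append(
                    BondEvent(self.step_count, rule.name, o1, self.site_slot(s1),
                              o2, self.site_slot(s2), BROKEN)
                )
        return events


# ---------------------------------------------------------------------------
# The integrator kernel (numba-accelerated when available)
# ---------------------------------------------------------------------------

def _bd_chunk_impl(pos, F, free_idx, noise,
                   bond_i, bond_j, bond_r0, bond_k,
                   pair_i, pair_j, pair_sig, eps, fcap,
                   trip_i, trip_j, trip_k, trip_th0, angle_k,
                   gm, gstart, gfixed, grotfree, gcen, goff, ginvgrot,
                   gnoise, grnoise,
                   box_lo, box_hi, mob, drag_c, drag_R, drag_k, max_step):
    nsteps = noise.shape[0]
    npart = pos.shape[0]
    G = gstart.shape[0] - 1
    rc_fac = 1.1224620483089301  # 2**(1/6)
    maxdisp = 0.0
    for t in range(nsteps):
        for i in range(npart):
            F[i, 0] = 0.0
            F[i, 1] = 0.0
            F[i, 2] = 0.0
        for b in range(bond_i.shape[0]):
            i = bond_i[b]
            j = bond_j[b]
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            if r > 1e-12:
                c = bond_k * (r - bond_r0[b]) / r
                F[i, 0] += c * dx
                F[i, 1] += c * dy
                F[i, 2] += c * dz
                F[j, 0] -= c * dx
                F[j, 1] -= c * dy
                F[j, 2] -= c * dz
        for p in range(pair_i.shape[0]):
            i = pair_i[p]
            j = pair_j[p]
            sig = pair_sig[p]
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            rc = sig * rc_fac
            if r2 < rc * rc and r2 > 1e-12:
                sr2 = (sig * sig) / r2
                sr6 = sr2 * sr2 * sr2
                f_over_r = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
                r = math.sqrt(r2)
                if f_over_r * r > fcap:
                    f_over_r = fcap / r
                F[j, 0] += f_over_r * dx
                F[j, 1] += f_over_r * dy
                F[j, 2] += f_over_r * dz
                F[i, 0] -= f_over_r * dx
                F[i, 1] -= f_over_r * dy
                F[i, 2] -= f_over_r * dz
        if angle_k > 0.0:
            for a in range(trip_j.shape[0]):
                i = trip_i[a]
                j = trip_j[a]
                k = trip_k[a]
                r1x = pos[i, 0] - pos[j, 0]
                r1y = pos[i, 1] - pos[j, 1]
                r1z = pos[i, 2] - pos[j, 2]
                r2x = pos[k, 0] - pos[j, 0]
                r2y = pos[k, 1] - pos[j, 1]
                r2z = pos[k, 2] - pos[j, 2]
                n1 = math.sqrt(r1x * r1x + r1y * r1y + r1z * r1z)
                n2 = math.sqrt(r2x * r2x + r2y * r2y + r2z * r2z)
                if n1 < 1e-9 or n2 < 1e-9:
                    continue
                cth = (r1x * r2x + r1y * r2y + r1z * r2z) / (n1 * n2)
                if cth > 1.0:
                    cth = 1.0
                if cth < -1.0:
                    cth = -1.0
                th = math.acos(cth)
                sth = math.sqrt(1.0 - cth * cth)
                if sth < 1e-6:
                    continue
                coef = -angle_k * (th - trip_th0[a]) / sth
                # dtheta/dr derivatives
                f1x = coef * (r2x / (n1 * n2) - cth * r1x / (n1 * n1))
                f1y = coef * (r2y / (n1 * n2) - cth * r1y / (n1 * n1))
                f1z = coef * (r2z / (n1 * n2) - cth * r1z / (n1 * n1))
                f2x = coef * (r1x / (n1 * n2) - cth * r2x / (n2 * n2))
                f2y = coef * (r1y / (n1 * n2) - cth * r2y / (n2 * n2))
                f2z = coef * (r1z / (n1 * n2) - cth * r2z / (n2 * n2))
                F[i, 0] += f1x
                F[i, 1] += f1y
                F[i, 2] += f1z
                F[k, 0] += f2x
                F[k, 1] += f2y
                F[k, 2] += f2z
                F[j, 0] -= f1x + f2x
                F[j, 1] -= f1y + f2y
                F[j, 2] -= f1z + f2z
        if drag_k > 0.0:
            for i in range(npart):
                dx = pos[i, 0] - drag_c[0]
                dy = pos[i, 1] - drag_c[1]
                dz = pos[i, 2] - drag_c[2]
                r = math.sqrt(dx * dx + dy * dy + dz * dz)
                if r > drag_R and r > 1e-12:
                    c = drag_k * (r - drag_R) / r
                    F[i, 0] -= c * dx
                    F[i, 1] -= c * dy
                    F[i, 2] -= c * dz
        # free particles: integrate + reflect
        for u in range(free_idx.shape[0]):
            i = free_idx[u]
            for d in range(3):
                step = F[i, d] * mob + noise[t, u, d]
                if step > max_step:
                    step = max_step
                elif step < -max_step:
                    step = -max_step
                if abs(step) > maxdisp:
                    maxdisp = abs(step)
                x = pos[i, d] + step
                if x < box_lo[d]:
                    x = 2.0 * box_lo[d] - x
                if x > box_hi[d]:
                    x = 2.0 * box_hi[d] - x
                pos[i, d] = x
        # rigid groups: net force -> translation, torque -> rotation
        for g in range(G):
            s = gstart[g]
            e = gstart[g + 1]
            n = e - s
            if gfixed[g] == 0:
                fx = 0.0
                fy = 0.0
                fz = 0.0
                for m in range(s, e):
                    i = gm[m]
                    fx += F[i, 0]
                    fy += F[i, 1]
                    fz += F[i, 2]
                dxc = fx * mob / n + gnoise[t, g, 0]
                dyc = fy * mob / n + gnoise[t, g, 1]
                dzc = fz * mob / n + gnoise[t, g, 2]
                if dxc > max_step:
                    dxc = max_step
                elif dxc < -max_step:
                    dxc = -max_step
                if dyc > max_step:
                    dyc = max_step
                elif dyc < -max_step:
                    dyc = -max_step
                if dzc > max_step:
                    dzc = max_step
                elif dzc < -max_step:
                    dzc = -max_step
                gcen[g, 0] += dxc
                gcen[g, 1] += dyc
                gcen[g, 2] += dzc
                st = math.sqrt(dxc * dxc + dyc * dyc + dzc * dzc)
                if st > maxdisp:
                    maxdisp = st
            if grotfree[g] == 1:
                tx = grnoise[t, g, 0]
                ty = grnoise[t, g, 1]
                tz = grnoise[t, g, 2]
                for m in range(s, e):
                    i = gm[m]
                    ox = goff[m, 0]
                    oy = goff[m, 1]
                    oz = goff[m, 2]
                    tx += (oy * F[i, 2] - oz * F[i, 1]) * ginvgrot[g]
                    ty += (oz * F[i, 0] - ox * F[i, 2]) * ginvgrot[g]
                    tz += (ox * F[i, 1] - oy * F[i, 0]) * ginvgrot[g]
                ang = math.sqrt(tx * tx + ty * ty + tz * tz)
                if ang > 1e-12:
                    ux = tx / ang
                    uy = ty / ang
                    uz = tz / ang
                    ca = math.cos(ang)
                    sa = math.sin(ang)
                    for m in range(s, e):
                        ox = goff[m, 0]
                        oy = goff[m, 1]
                        oz = goff[m, 2]
                        dot = ux * ox + uy * oy + uz * oz
                        cx = uy * oz - uz * oy
                        cy = uz * ox - ux * oz
                        cz = ux * oy - uy * ox
                        goff[m, 0] = ox * ca + cx * sa + ux * dot * (1.0 - ca)
                        goff[m, 1] = oy * ca + cy * sa + uy * dot * (1.0 - ca)
                        goff[m, 2] = oz * ca + cz * sa + uz * dot * (1.0 - ca)
            for m in range(s, e):
                i = gm[m]
                pos[i, 0] = gcen[g, 0] + goff[m, 0]
                pos[i, 1] = gcen[g, 1] + goff[m, 1]
                pos[i, 2] = gcen[g, 2] + goff[m, 2]
    return maxdisp


if _HAVE_NUMBA:
    _bd_chunk = njit(cache=True, fastmath=False)(_bd_chunk_impl)
else:  # pragma: no cover
    _bd_chunk = _bd_chunk_impl


# ---------------------------------------------------------------------------
# Module-level operations
# ---------------------------------------------------------------------------

def init_world(model: ModelDef, geometry: dict, box, counts: dict | None = None,
               templates: dict | None = None, placements: list | None = None,
               placement_ranges=None, seed: int = 0, force: ForceParams | None = None,
               seeded_growth: bool = False, max_tries: int = 200) -> WorldState:
    """Create a world, honoring explicit placements and placing ``counts``
    randomly (without overlap) inside ``placement_ranges`` (default: the box).

    ``counts`` maps a molecule type *or* template name to a copy number;
    ``placements`` is a list of ``(name, center)`` honored exactly, placed
    before random copies.  Raises after ``max_tries`` failed placement
    attempts per copy (box too small / too crowded).
    """
    world = WorldState(model, geometry, box, seed=seed, force=force,
                       seeded_growth=seeded_growth)
    templates = templates or {}
    ranges = np.asarray(placement_ranges if placement_ranges is not None else world.box,
                        dtype=float).reshape(3, 2)

    def place(name, center, rotation=None):
        if name in templates:
            return world.add_template_instance(templates[name], center, rotation=rotation)
        return [world.add_molecule(name, center)]

    for name, center in placements or []:
        place(name, center)
    for name, count in (counts or {}).items():
        if count < 0:
            raise ValueError(f"negative copy count for {name!r}")
        if name in templates:
            rad = float(np.max(np.linalg.norm(
                templates[name].positions - templates[name].positions.mean(axis=0), axis=1
            )) + templates[name].radii.max())
        else:
            rad = world.geometry[name].radius
        for _ in range(count):
            for attempt in range(max_tries):
                center = world.rng.uniform(ranges[:, 0], ranges[:, 1])
                if world.n_particles:
                    dmin = float(np.min(
                        np.linalg.norm(world.pos - center[None, :], axis=1)
                        - world.radius
                    ))
                    if dmin < 0.6 * rad:
                        continue
                rot = _random_rotation(world.rng) if name in templates else None
                place(name, center, rotation=rot)
                break
            else:
                raise RuntimeError(
                    f"could not place a copy of {name!r} after {max_tries} tries "
                    "(reactor too small or too crowded)"
                )
    return world


def _random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def step_dynamics(world: WorldState, n_steps: int = 1) -> WorldState:
    world.advance(n_steps)
    return world


def fire_reactions(world: WorldState):
    return world, world.fire_reactions()


def run_protocol(world: WorldState, protocol: SimProtocol, templates: dict | None = None,
                 snapshot_hook=None):
    """Execute a protocol; returns ``(snapshots, bond events)``.

    Snapshots (``trajectory_io.TrajectoryRecord``) are taken at step 0, every
    ``dump_interval`` steps during run phases, and after the final phase.
    The same seed always yields a bit-identical trajectory and bond log.
    """
    from .trajectory_io import TrajectoryRecord

    templates = templates or {}
    snapshots = [TrajectoryRecord.from_world(world)]
    if snapshot_hook:
        snapshot_hook(snapshots[-1])
    start_events = len(world.bond_log)
    for phase in protocol.phases:
        if phase[0] == "run":
            remaining = int(phase[1])
            next_dump = ((world.step_count // protocol.dump_interval) + 1) * protocol.dump_interval
            while remaining > 0:
                chunk = min(world.react_interval, remaining, next_dump - world.step_count)
                world.advance(chunk)
                remaining -= chunk
                world.fire_reactions()
                if world.step_count >= next_dump:
                    snapshots.append(TrajectoryRecord.from_world(world))
                    if snapshot_hook:
                        snapshot_hook(snapshots[-1])
                    next_dump += protocol.dump_interval
        elif phase[0] == "add":
            _, count, name = phase
            for _ in range(count):
                _place_random(world, name, templates)
        elif phase[0] == "switch":
            world.switches[phase[1]] = bool(phase[2])
        elif phase[0] == "force":
            setattr(world.force, phase[1], phase[2])
            world._dirty = True
        else:
            raise ValueError(f"unknown protocol phase {phase[0]!r}")
    if snapshots[-1].step != world.step_count:
        snapshots.append(TrajectoryRecord.from_world(world))
        if snapshot_hook:
            snapshot_hook(snapshots[-1])
    return snapshots, world.bond_log[start_events:]


def _place_random(world: WorldState, name: str, templates: dict, max_tries: int = 200):
    ranges = world.box
    for _ in range(max_tries):
        center = world.rng.uniform(ranges[:, 0], ranges[:, 1])
        rad = (world.geometry[name].radius if name not in templates
               else float(templates[name].radii.max()))
        if world.n_particles:
            dmin = float(np.min(
                np.linalg.norm(world.pos - center[None, :], axis=1) - world.radius
            ))
            if dmin < 0.6 * rad:
                continue
        if name in templates:
            world.add_template_instance(templates[name], center,
                                        rotation=_random_rotation(world.rng))
        else:
            world.add_molecule(name, center)
        return
    raise RuntimeError(f"could not place {name!r}")
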