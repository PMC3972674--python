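"""Structural analysis of replicate simulations.

Three root-mean-square deviations compare two structures ``p`` and ``q``
(same particles, same order):

* positional RMSD — after removing translational freedom (anchor particle at
  the origin in both structures) and rotational freedom (aligning the rays
  from the anchor to two further reference particles),
  ``sqrt(mean_i ||p_i - q_i||^2)``;
* paired RMSD — the RMSD of all pairwise inter-particle distances,
  ``sqrt( 2/(n^2+n) * sum_{i} sum_{j<=i} (||p_i-p_j|| - ||q_i-q_j||)^2 )``,
  invariant under rigid motion of either structure;
* local RMSD — paired RMSD with every distance clipped at a cutoff ``C``,
  ignoring macrostructure beyond that scale.

A matrix of pairwise structure distances is clustered with UPGMA (average
linkage, cluster-size weighted) into an ultrametric dendrogram.  Bond-level
statistics summarize which rules were realized how often across replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "rmsd_positions",
    "paired_rmsd",
    "local_rmsd",
    "StructureDistanceMatrix",
    "distance_matrix",
    "DendrogramNode",
    "upgma",
    "bond_frequency",
    "bond_frequency_over_time",
    "max_bond_capacity",
    "bond_count_histogram",
    "bridge_count",
    "rosette_bridge_count",
]


def _pairwise(p: np.ndarray) -> np.ndarray:
    d = p[:, None, :] - p[None, :, :]
    return np.sqrt(np.sum(d * d, axis=-1))


def rmsd_positions(p, q, anchor=(0, 1, 2)) -> float:
    """Positional RMSD after two-ray anchor alignment.

    The anchor triple ``(a0, a1, a2)`` fixes the gauge: ``a0`` is moved to
    the origin in both structures, ``q`` is rotated so the ray to ``a1``
    coincides with that of ``p``, then rotated about that ray so ``a2`` lies
    in the same half-plane.  Anchors must be non-collinear.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("structures must have the same particle count")
    a0, a1, a2 = anchor
    p = p - p[a0]
    q = q - q[a0]
    for x in (p, q):
        v1, v2 = x[a1], x[a2]
        if np.linalg.norm(v1) < 1e-12 or np.linalg.norm(np.cross(v1, v2)) < 1e-12:
            raise ValueError("anchor particles are collinear or coincident")
    q = q @ _two_ray_rotation(q[a1], q[a2], p[a1], p[a2]).T
    return float(np.sqrt(np.mean(np.sum((p - q) ** 2, axis=1))))


def _two_ray_rotation(u1, u2, v1, v2) -> np.ndarray:
    """Rotation taking ray u1 onto ray v1 and u2 into the (v1, v2) half-plane."""
    r1 = _rotation_between(u1, v1)
    u2r = r1 @ u2
    axis = v1 / np.linalg.norm(v1)
    # project both second rays into the plane orthogonal to the aligned axis
    a = u2r - axis * (u2r @ axis)
    b = v2 - axis * (v2 @ axis)
    if np.linalg.norm(a) < 1e-12 or np.linalg.norm(b) < 1e-12:
        return r1
    cosang = float(np.clip(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)), -1.0, 1.0))
    sign = 1.0 if np.dot(np.cross(a, b), axis) >= 0 else -1.0
    return _axis_angle(axis, sign * math.acos(cosang)) @ r1


def _rotation_between(u, v) -> np.ndarray:
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.clip(u @ v, -1.0, 1.0))
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite rays: rotate by pi around any perpendicular axis
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        return _axis_angle(perp / np.linalg.norm(perp), math.pi)
    return _axis_angle(axis / s, math.atan2(s, c))


def _axis_angle(axis, angle) -> np.ndarray:
    x, y, z = axis
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + math.sin(angle) * K + (1.0 - math.cos(angle)) * (K @ K)


def paired_rmsd(p, q) -> float:
    """RMSD of pairwise inter-particle distances (rigid-motion invariant).

    Averages over the n(n+1)/2 ordered pairs ``j <= i`` (the diagonal terms
    vanish), with prefactor ``2/(n^2+n)``.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("structures must have the same particle count")
    n = p.shape[0]
    if n == 0:
        raise ValueError("empty structure")
    diff = _pairwise(p) - _pairwise(q)
    # each unordered pair appears twice in the full matrix; diagonal is zero
    ssq = float(np.sum(np.tril(diff) ** 2))
    return math.sqrt(2.0 / (n * n + n) * ssq)


def local_rmsd(p, q, cutoff: float) -> float:
    """Paired RMSD with distances clipped at ``cutoff`` (Å): only local
    structure below the cutoff scale contributes."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("structures must have the same particle count")
    n = p.shape[0]
    diff = np.minimum(cutoff, _pairwise(p)) - np.minimum(cutoff, _pairwise(q))
    ssq = float(np.sum(np.tril(diff) ** 2))
    return math.sqrt(2.0 / (n * n + n) * ssq)


@dataclass
class StructureDistanceMatrix:
    labels: list
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T) or np.any(np.diag(m) != 0) or np.any(m < 0):
            raise ValueError("distance matrix must be symmetric, zero-diagonal, non-negative")
        self.matrix = m

    def to_tsv(self, sink) -> None:
        import pandas as pd

        pd.DataFrame(self.matrix, index=self.labels, columns=self.labels).to_csv(
            sink, sep="\t"
        )


def distance_matrix(snapshots, metric="paired", cutoff: float | None = None,
                    anchor=(0, 1, 2), labels=None) -> StructureDistanceMatrix:
    """Pairwise structure distances over ``snapshots`` (list of (n,3) arrays).

    ``metric``: ``"rmsd"`` (anchored positional), ``"paired"`` or
    ``"local"`` (requires ``cutoff``).
    """
    snaps = [np.asarray(s, dtype=float) for s in snapshots]
    if len(snaps) < 2:
        raise ValueError("need at least two snapshots")
    n = snaps[0].shape
    for s in snaps:
        if s.shape != n:
            raise ValueError("snapshots have inconsistent particle sets")
    if metric == "rmsd":
        f = lambda a, b: rmsd_positions(a, b, anchor)
    elif metric == "paired":
        f = paired_rmsd
    elif metric == "local":
        if cutoff is None:
            raise ValueError("local metric needs a cutoff")
        f = lambda a, b: local_rmsd(a, b, cutoff)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    m = np.zeros((len(snaps), len(snaps)))
    for i in range(len(snaps)):
        for j in range(i + 1, len(snaps)):
            m[i, j] = m[j, i] = f(snaps[i], snaps[j])
    labels = list(labels) if labels is not None else list(range(len(snaps)))
    return StructureDistanceMatrix(labels, m)


@dataclass
class DendrogramNode:
    """A node of an ultrametric dendrogram: leaves carry a label, inner nodes
    carry the merge height (average inter-cluster distance)."""

    height: float = 0.0
    label: object = None
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf:
            return [self.label]
        return [l for c in self.children for l in c.leaves()]

    def cophenetic(self) -> dict:
        """Map frozenset({label_a, label_b}) -> merge height."""
        out: dict = {}

        def walk(node):
            if node.is_leaf:
                return [node.label]
            groups = [walk(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            out[frozenset((a, b))] = node.height
            return [l for g in groups for l in g]

        walk(self)
        return out

    def to_newick(self) -> str:
        def fmt(node, parent_height):
            blen = parent_height - (0.0 if node.is_leaf else node.height)
            if node.is_leaf:
                return f"{node.label}:{blen:.6g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{blen:.6g}"

        if self.is_leaf:
            return f"{self.label};"
        inner = ",".join(fmt(c, self.height) for c in self.children)
        return f"({inner});"


def upgma(dist) -> DendrogramNode:
    """UPGMA agglomeration of a distance matrix.

    Average linkage weighted by cluster size; merge height is the average
    inter-cluster distance (not halved).  Ties break on the smallest label
    pair, so the tree is deterministic.
    """
    if isinstance(dist, StructureDistanceMatrix):
        labels, m = dist.labels, dist.matrix.copy()
    else:
        m = np.asarray(dist, dtype=float).copy()
        labels = list(range(m.shape[0]))
    n = m.shape[0]
    if n < 2 or m.shape != (n, n):
        raise ValueError("need a square distance matrix of size >= 2")
    clusters = {i: DendrogramNode(label=labels[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    d = {frozenset((i, j)): float(m[i, j]) for i in range(n) for j in range(i + 1, n)}
    nxt = n
    while len(active) > 1:
        best = min(
            ((d[frozenset((i, j))], (i, j)) for ii, i in enumerate(active)
             for j in active[ii + 1:]),
            key=lambda t: (t[0], t[1]),
        )
        h, (i, j) = best
        node = DendrogramNode(height=h, children=[clusters[i], clusters[j]])
        si, sj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            dik = d[frozenset((i, k))]
            djk = d[frozenset((j, k))]
            d[frozenset((nxt, k))] = (si * dik + sj * djk) / (si + sj)
        active = [k for k in active if k not in (i, j)] + [nxt]
        clusters[nxt] = node
        sizes[nxt] = si + sj
        nxt += 1
    return clusters[active[0]]


# ---------------------------------------------------------------------------
# Bond statistics over replicate runs
# ---------------------------------------------------------------------------

def max_bond_capacity(rule, copy_numbers: dict, sites_per_partner: int = 1) -> int:
    """Per-run maximum number of bonds a bind rule can realize: the smaller
    of the two partners' capacities (copy number x site multiplicity)."""
    mols = rule.lhs_molecules
    if len(mols) != 2:
        raise ValueError(f"rule {rule.name!r} is not a two-partner bind rule")
    caps = []
    for m in mols:
        if m.type_name not in copy_numbers:
            raise KeyError(f"no copy number for {m.type_name!r}")
        caps.append(copy_numbers[m.type_name] * sites_per_partner)
    return min(caps)


def final_bond_counts(events, rules=None) -> dict:
    """Net (formed - broken) bond count per rule name at the end of a log."""
    counts: dict = {}
    for ev in events:
        counts[ev.rule] = counts.get(ev.rule, 0) + (1 if ev.action == "formed" else -1)
    if rules is not None:
        known = {r.name for r in rules}
        unknown = set(counts) - known
        if unknown:
            raise KeyError(f"bond log references unknown rule(s) {sorted(unknown)}")
        for r in rules:
            counts.setdefault(r.name, 0)
    return counts


def bond_frequency(bond_logs, model, copy_numbers: dict) -> dict:
    """Realized fraction per bind rule over replicate runs, in percent.

    For each rule: bonds present at the final step summed over runs, divided
    by the maximum possible over runs (runs x per-run capacity, the capacity
    being the smaller partner's copy count x site multiplicity).
    """
    bind_rules = [r for r in model.rules if r.kind == "bind"]
    totals = {r.name: 0 for r in bind_rules}
    for events in bond_logs:
        counts = final_bond_counts(events, rules=model.rules)
        for r in bind_rules:
            totals[r.name] += counts.get(r.name, 0)
    out = {}
    nruns = len(bond_logs)
    for r in bind_rules:
        cap = max_bond_capacity(r, copy_numbers) * nruns
        out[r.name] = 100.0 * totals[r.name] / cap if cap else 0.0
    return out


def bond_frequency_over_time(bond_logs, model, copy_numbers: dict, steps) -> dict:
    """Time-resolved realized fraction per bind rule, in percent.

    For each requested step the net bond count of events up to and including
    that step is used; the last time point reproduces the static
    :func:`bond_frequency` when it covers the whole log.
    """
    bind_rules = [r for r in model.rules if r.kind == "bind"]
    steps = list(steps)
    nruns = len(bond_logs)
    totals = {r.name: np.zeros(len(steps)) for r in bind_rules}
    for events in bond_logs:
        final_bond_counts(events, rules=model.rules)  # validates rule names
        for r in bind_rules:
            running = 0
            ev_idx = 0
            evs = [e for e in events if e.rule == r.name]
            for si, t in enumerate(steps):
                while ev_idx < len(evs) and evs[ev_idx].step <= t:
                    running += 1 if evs[ev_idx].action == "formed" else -1
                    ev_idx += 1
                totals[r.name][si] += running
    out = {}
    for r in bind_rules:
        cap = max_bond_capacity(r, copy_numbers) * nruns
        out[r.name] = (100.0 * totals[r.name] / cap) if cap else totals[r.name] * 0.0
    return out


def bond_count_histogram(counts, max_per_run: int) -> dict:
    """Distribution of per-run final bond counts: fraction of runs with each
    count 0..max; fractions sum to 1."""
    counts = list(counts)
    if not counts:
        raise ValueError("no runs")
    for c in counts:
        if c > max_per_run:
            raise ValueError(f"count {c} exceeds the per-run maximum {max_per_run}")
    hist = {k: 0 for k in range(max_per_run + 1)}
    for c in counts:
        hist[c] += 1
    return {k: v / len(counts) for k, v in hist.items()}


def bridge_count(bonds, anchor_groups, n_particles: int | None = None):
    """Bridges between anchor groups through non-anchor particles.

    ``bonds`` is an iterable of particle pairs (or 4-tuples ``(a, sa, b,
    sb)``); ``anchor_groups`` a list of disjoint particle-id sets (e.g. the
    nucleosomes).  A pair of groups counts as bridged when a bond path
    connects them without passing through any other anchor group's
    particles.  Returns ``(count, {frozenset((gi, gj)): bool})``.
    """
    pairs = []
    for b in bonds:
        if len(b) == 4:
            pairs.append((b[0], b[2]))
        else:
            pairs.append((b[0], b[1]))
    groups = [set(g) for g in anchor_groups]
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            if groups[gi] & groups[gj]:
                raise ValueError("anchor groups must be disjoint")
    adj: dict = {}
    for a, b in pairs:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    member: dict = {}
    for gi, g in enumerate(groups):
        for p in g:
            member[p] = gi
    connectivity = {}
    count = 0
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            blocked = set().union(*(groups[k] for k in range(len(groups)) if k not in (gi, gj)))
            seen = set(groups[gi])
            stack = list(groups[gi])
            found = False
            while stack and not found:
                u = stack.pop()
                for v in adj.get(u, ()):
                    if v in blocked or v in seen:
                        continue
                    if v in groups[gj]:
                        found = True
                        break
                    # paths run through non-anchor particles only
                    if member.get(v, -1) == -1 or v in groups[gi]:
                        seen.add(v)
                        stack.append(v)
            connectivity[frozenset((gi, gj))] = found
            count += int(found)
    return count, connectivity


def rosette_bridge_count(bonds, anchor_groups) -> int:
    """Number of bridges joining the anchor groups into connected structures.

    A rosette of seven nucleosomes assembled into a single structure is held
    together by six bridges (each joining two nucleosomes); additional links
    between already-joined nucleosomes are cross-links, not new bridges.
    Operationally this is the spanning count: ``n_groups`` minus the number
    of connected components of the anchor-contracted bond graph.
    """
    pairs = [(b[0], b[2]) if len(b) == 4 else (b[0], b[1]) for b in bonds]
    groups = [set(g) for g in anchor_groups]
    rep = {}
    for gi, g in enumerate(groups):
        for p in g:
            rep[p] = ("g", gi)
    parent: dict = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for gi in range(len(groups)):
        find(("g", gi))
    for a, b in pairs:
        union(rep.get(a, a), rep.get(b, b))
    roots = {find(("g", gi)) for gi in range(len(groups))}
    return len(groups) - len(roots)
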