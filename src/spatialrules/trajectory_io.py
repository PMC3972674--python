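"""Snapshot, bond-log and bond-network output.

Snapshots use an extended-XYZ dialect: a particle-count line, a key=value
comment line (``step``, ``box``, ``seed`` and the bond list), then one line
per particle (``type x y z id group``) — readable by common molecular
viewers, and losslessly round-tripped by :func:`read_snapshot`.  Bond-event
logs are tab-separated (``step rule idA siteA idB siteB action``).  Bond
networks are emitted as Graphviz DOT text.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .events import BondEvent

__all__ = [
    "TrajectoryRecord",
    "write_snapshot",
    "read_snapshot",
    "write_trajectory",
    "read_trajectory",
    "write_bond_log",
    "read_bond_log",
    "write_bond_network",
]


@dataclass
class TrajectoryRecord:
    """One snapshot: step, box, per-particle rows and the bond list.

    ``bonds`` entries are ``(idA, siteA, idB, siteB)`` with type-level site
    slots; particle ids are stable across the records of one run.
    """

    step: int
    box: np.ndarray  # (3, 2)
    seed: int
    ids: np.ndarray
    types: list
    pos: np.ndarray
    groups: np.ndarray
    bonds: list = field(default_factory=list)

    @classmethod
    def from_world(cls, world) -> "TrajectoryRecord":
        bonds = [
            (world.site_owner(a), world.site_slot(a), world.site_owner(b), world.site_slot(b))
            for a, b in world.bond_pairs()
        ]
        return cls(
            step=world.step_count,
            box=world.box.copy(),
            seed=world.seed,
            ids=np.arange(world.n_particles),
            types=[world.particle_type_name(i) for i in range(world.n_particles)],
            pos=world.pos.copy(),
            groups=world.group_id.copy(),
            bonds=bonds,
        )

    def __eq__(self, other):
        return (
            isinstance(other, TrajectoryRecord)
            and self.step == other.step
            and self.seed == other.seed
            and np.allclose(self.box, other.box)
            and np.array_equal(self.ids, other.ids)
            and self.types == other.types
            and np.allclose(self.pos, other.pos, atol=0.0)
            and np.array_equal(self.groups, other.groups)
            and sorted(self.bonds) == sorted(other.bonds)
        )


def write_snapshot(record: TrajectoryRecord, sink) -> None:
    """Write one extended-XYZ frame; ``sink`` is a path or text file object."""
    close, fh = _open(sink, "w")
    try:
        _write_frame(record, fh)
    finally:
        if close:
            fh.close()


def _write_frame(record: TrajectoryRecord, fh) -> None:
    n = len(record.ids)
    box = " ".join(f"{v:.6g}" for v in np.asarray(record.box).ravel())
    bonds = ",".join(f"{a}:{sa}:{b}:{sb}" for a, sa, b, sb in record.bonds)
    fh.write(f"{n}\n")
    fh.write(f'step={record.step} seed={record.seed} box="{box}" bonds="{bonds}"\n')
    for i in range(n):
        x, y, z = record.pos[i]
        fh.write(
            f"{record.types[i]} {x:.8f} {y:.8f} {z:.8f} {int(record.ids[i])} {int(record.groups[i])}\n"
        )


def read_snapshot(source) -> TrajectoryRecord:
    """Read one frame written by :func:`write_snapshot`."""
    frames = read_trajectory(source, limit=1)
    if not frames:
        raise ValueError("no frame found")
    return frames[0]


def write_trajectory(records, sink) -> None:
    close, fh = _open(sink, "w")
    try:
        for rec in records:
            _write_frame(rec, fh)
    finally:
        if close:
            fh.close()


def read_trajectory(source, limit: int | None = None) -> list:
    close, fh = _open(source, "r")
    try:
        frames = []
        while limit is None or len(frames) < limit:
            header = fh.readline()
            if not header.strip():
                break
            try:
                n = int(header)
            except ValueError as e:
                raise ValueError(f"malformed frame header {header!r}") from e
            comment = fh.readline()
            meta = _parse_comment(comment)
            ids = np.empty(n, dtype=int)
            groups = np.empty(n, dtype=int)
            pos = np.empty((n, 3))
            types = []
            for k in range(n):
                line = fh.readline()
                parts = line.split()
                if len(parts) != 6:
                    raise ValueError(f"malformed particle line {line!r} (count mismatch?)")
                types.append(parts[0])
                pos[k] = [float(v) for v in parts[1:4]]
                ids[k] = int(parts[4])
                groups[k] = int(parts[5])
            frames.append(
                TrajectoryRecord(
                    step=int(meta.get("step", 0)),
                    box=np.array([float(v) for v in meta.get("box", "0 0 0 0 0 0").split()]).reshape(3, 2),
                    seed=int(meta.get("seed", 0)),
                    ids=ids,
                    types=types,
                    pos=pos,
                    groups=groups,
                    bonds=[
                        tuple(int(v) for v in ent.split(":"))
                        for ent in meta.get("bonds", "").split(",")
                        if ent
                    ],
                )
            )
        return frames
    finally:
        if close:
            fh.close()


def _parse_comment(comment: str) -> dict:
    meta = {}
    pos = 0
    while pos < len(comment):
        eq = comment.find("=", pos)
        if eq < 0:
            break
        key = comment[pos:eq].strip()
        if comment[eq + 1] == '"':
            end = comment.find('"', eq + 2)
            meta[key] = comment[eq + 2:end]
            pos = end + 1
        else:
            end = comment.find(" ", eq + 1)
            if end < 0:
                end = len(comment)
            meta[key] = comment[eq + 1:end].strip()
            pos = end
    return meta


def write_bond_log(events, sink) -> None:
    """Tab-separated bond-event log: step rule idA siteA idB siteB action."""
    close, fh = _open(sink, "w")
    try:
        fh.write("step\trule\tidA\tsiteA\tidB\tsiteB\taction\n")
        for ev in events:
            fh.write(
                f"{ev.step}\t{ev.rule}\t{ev.a_particle}\t{ev.a_site}\t"
                f"{ev.b_particle}\t{ev.b_site}\t{ev.action}\n"
            )
    finally:
        if close:
            fh.close()


def read_bond_log(source) -> list:
    close, fh = _open(source, "r")
    try:
        header = fh.readline()
        if not header.startswith("step\t"):
            raise ValueError("missing bond-log header")
        events = []
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise ValueError(f"malformed bond-log line {line!r}")
            events.append(
                BondEvent(int(parts[0]), parts[1], int(parts[2]), int(parts[3]),
                          int(parts[4]), int(parts[5]), parts[6])
            )
        return events
    finally:
        if close:
            fh.close()


def write_bond_network(world_or_record, sink=None) -> str:
    """Graphviz DOT text of the bond network: one node per particle (labelled
    with its type), one undirected edge per bond, nodes ordered by id."""
    if isinstance(world_or_record, TrajectoryRecord):
        rec = world_or_record
    else:
        rec = TrajectoryRecord.from_world(world_or_record)
    lines = ["graph bonds {"]
    for i, t in zip(rec.ids, rec.types):
        lines.append(f'  n{int(i)} [label="{t}"];')
    for a, _, b, _ in sorted(rec.bonds):
        lines.append(f"  n{a} -- n{b};")
    lines.append("}")
    text = "\n".join(lines) + "\n"
    if sink is not None:
        close, fh = _open(sink, "w")
        try:
            fh.write(text)
        finally:
            if close:
                fh.close()
    return text


def _open(target, mode):
    if isinstance(target, (str, bytes)) or hasattr(target, "__fspath__"):
        return True, open(target, mode)
    if isinstance(target, io.TextIOBase) or hasattr(target, "write") or hasattr(target, "read"):
        return False, target
    raise TypeError(f"cannot open {target!r}")
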