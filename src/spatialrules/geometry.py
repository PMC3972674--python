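"""Molecular geometry: sphere radii from mass, site placement, templates.

Every elementary molecule is a sphere.  When no measured radius is available
the radius follows from the molecular mass under a constant-density
assumption, calibrated so that histone H3 (15 kDa) has a 15.00 Å radius:
``r(m) = r_ref * (m / m_ref)**(1/3)``.

Binding sites sit on the sphere surface in spherical coordinates: ``phi`` is
the angle from the zenith (+z) axis, ``theta`` the azimuth around it, and
``length`` the bond reach (default: the molecule radius, i.e. reactions
happen on the surface).  A site without declared angles is isotropic — the
whole surface is equally reactive and no angular veto applies.

Structural templates assemble several spheres at fixed relative coordinates;
a template may be rigid (shape preserved exactly during simulation) and/or
anchored at a fixed position (optionally still free to rotate).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "H3_REF_MASS_KDA",
    "H3_REF_RADIUS_A",
    "SitePlacement",
    "GeometrySpec",
    "TemplateDef",
    "TemplateMember",
    "BuiltTemplate",
    "radius_from_mass",
    "site_to_cartesian",
    "build_template",
    "read_geometry_table",
    "read_template_table",
]

H3_REF_MASS_KDA = 15.0
H3_REF_RADIUS_A = 15.0


def radius_from_mass(
    mass: float, ref_mass: float = H3_REF_MASS_KDA, ref_radius: float = H3_REF_RADIUS_A
) -> float:
    """Sphere radius in Å for a molecule of ``mass`` kDa (constant density).

    ``r = r_ref * (m / m_ref)**(1/3)`` — cube-root scaling calibrated to the
    histone H3 reference pair (15 kDa, 15.00 Å).
    """
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    if ref_mass <= 0 or ref_radius <= 0:
        raise ValueError("reference mass and radius must be positive")
    return ref_radius * (mass / ref_mass) ** (1.0 / 3.0)


def site_to_cartesian(phi: float, theta: float, length: float) -> np.ndarray:
    """Body-frame offset of a site at spherical angles (degrees) and reach Å.

    ``phi`` is measured from the zenith (+z); ``theta`` rotates around it.
    """
    if not 0.0 <= phi <= 180.0:
        raise ValueError(f"phi must be in [0, 180] degrees, got {phi}")
    if not 0.0 <= theta < 360.0:
        raise ValueError(f"theta must be in [0, 360) degrees, got {theta}")
    if length <= 0:
        raise ValueError(f"site length must be positive, got {length}")
    p, t = math.radians(phi), math.radians(theta)
    return np.array(
        [length * math.sin(p) * math.cos(t), length * math.sin(p) * math.sin(t), length * math.cos(p)]
    )


@dataclass(frozen=True)
class SitePlacement:
    phi: float  # degrees from zenith
    theta: float  # degrees azimuth
    length: float  # Å bond reach
    dihedral: float | None = None  # degrees; supported in the data model, off by default

    def offset(self) -> np.ndarray:
        return site_to_cartesian(self.phi, self.theta, self.length)


@dataclass
class GeometrySpec:
    """Per-type geometry: mass (kDa), radius (Å) and optional site placement.

    ``site_placements`` maps a site name to a :class:`SitePlacement`; sites
    absent from the map are isotropic with reach equal to the radius.
    """

    type_name: str
    mass: float
    radius: float | None = None
    site_placements: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.radius is None:
            self.radius = radius_from_mass(self.mass)
        if self.radius <= 0:
            raise ValueError(f"{self.type_name}: radius must be positive")

    def site_length(self, site_name: str) -> float:
        pl = self.site_placements.get(site_name)
        return self.radius if pl is None else pl.length


@dataclass(frozen=True)
class TemplateMember:
    type_name: str
    position: tuple  # Å, relative coordinates


@dataclass
class TemplateDef:
    """A multi-particle structural template.

    ``internal_bonds`` lists ``(i, site_i, j, site_j)`` member-pair bonds that
    exist from the start; their rest length is the member distance in the
    template, so a relaxed template carries no internal stress.
    """

    name: str
    members: list  # of TemplateMember
    internal_bonds: list = field(default_factory=list)
    rigid: bool = False
    fixed_position: bool = False
    free_rotation: bool = False


@dataclass
class BuiltTemplate:
    name: str
    type_names: list
    positions: np.ndarray  # (n, 3) relative Å
    radii: np.ndarray
    internal_bonds: list  # (i, site_i, j, site_j, rest_length)
    rigid: bool
    fixed_position: bool
    free_rotation: bool


def build_template(tdef: TemplateDef, geometry: dict) -> BuiltTemplate:
    """Instantiate a template against a geometry table (type -> GeometrySpec).

    Raises on a member type without geometry; warns (but proceeds) when two
    members overlap by more than half the sum of their radii — rigid bodies
    such as nucleosomes are intentionally denser than free spheres.
    """
    missing = [m.type_name for m in tdef.members if m.type_name not in geometry]
    if missing:
        raise KeyError(f"template {tdef.name!r}: no geometry for member type(s) {missing}")
    pos = np.asarray([m.position for m in tdef.members], dtype=float).reshape(len(tdef.members), 3)
    radii = np.array([geometry[m.type_name].radius for m in tdef.members])
    for i in range(len(tdef.members)):
        for j in range(i + 1, len(tdef.members)):
            d = float(np.linalg.norm(pos[i] - pos[j]))
            if d < 0.5 * (radii[i] + radii[j]):
                warnings.warn(
                    f"template {tdef.name!r}: members {i} and {j} overlap "
                    f"(distance {d:.1f} Å < half the radius sum)",
                    stacklevel=2,
                )
    bonds = []
    for i, si, j, sj in tdef.internal_bonds:
        rest = float(np.linalg.norm(pos[i] - pos[j]))
        bonds.append((i, si, j, sj, rest))
    return BuiltTemplate(
        tdef.name,
        [m.type_name for m in tdef.members],
        pos,
        radii,
        bonds,
        tdef.rigid,
        tdef.fixed_position,
        tdef.free_rotation,
    )


# ---------------------------------------------------------------------------
# Table readers (the "geometry" and "structure templates" tables)
# ---------------------------------------------------------------------------

def read_geometry_table(source) -> dict:
    """Read a tab-separated geometry table into ``{type: GeometrySpec}``.

    Columns: ``type, mass_kDa`` and optionally ``radius_A`` (computed from
    mass when blank) plus per-site rows ``site, phi, theta, length``.  The
    first row of a type carries its mass/radius; additional rows add sites.
    """
    import pandas as pd

    df = pd.read_csv(source, sep="\t", comment="#", dtype=str).fillna("")
    if "type" not in df.columns or "mass_kDa" not in df.columns:
        raise ValueError("geometry table needs at least 'type' and 'mass_kDa' columns")
    specs: dict = {}
    for _, row in df.iterrows():
        name = row["type"]
        if name not in specs:
            radius = float(row["radius_A"]) if row.get("radius_A", "") else None
            specs[name] = GeometrySpec(name, float(row["mass_kDa"]), radius)
        spec = specs[name]
        if row.get("site", ""):
            length = float(row["length"]) if row.get("length", "") else spec.radius
            spec.site_placements[row["site"]] = SitePlacement(
                float(row["phi"]), float(row["theta"]), length
            )
    return specs


def read_template_table(source) -> dict:
    """Read a tab-separated template table into ``{name: TemplateDef}``.

    Columns: ``template, member_index, type, x, y, z, rigid, fixed`` and
    optionally ``free_rotation`` and ``bonds`` (semicolon-separated
    ``j:site_i:site_j`` entries bonding this member to member ``j``).
    """
    import pandas as pd

    df = pd.read_csv(source, sep="\t", comment="#", dtype=str).fillna("")
    out: dict = {}
    for tname, group in df.groupby("template", sort=False):
        group = group.sort_values("member_index", key=lambda s: s.astype(int))
        members = [
            TemplateMember(r["type"], (float(r["x"]), float(r["y"]), float(r["z"])))
            for _, r in group.iterrows()
        ]
        bonds = []
        for i, (_, r) in enumerate(group.iterrows()):
            for ent in str(r.get("bonds", "")).split(";"):
                if not ent.strip():
                    continue
                j_s, si, sj = ent.split(":")
                bonds.append((i, si, int(j_s), sj))
        first = group.iloc[0]
        out[tname] = TemplateDef(
            tname,
            members,
            internal_bonds=[(i, si, j, sj) for i, si, j, sj in bonds],
            rigid=str(first.get("rigid", "")).strip().lower() in ("1", "true", "yes"),
            fixed_position=str(first.get("fixed", "")).strip().lower() in ("1", "true", "yes"),
            free_rotation=str(first.get("free_rotation", "")).strip().lower() in ("1", "true", "yes"),
        )
    return out
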