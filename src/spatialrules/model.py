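"""Rule-based model language: molecule types, site patterns and reaction rules.

The model language is a documented subset of the BioNetGen language (BNGL):
molecule type declarations with named sites and modification states, and
unidirectional reaction rules written as site-graph patterns.  Omitted sites
are wildcards; a site written without a bond marker must be unbound; ``!n``
is a named bond, ``!+`` means bound to anything and ``!?`` leaves the bond
state unspecified; ``~label`` constrains the modification state.

Rules conserve molecules: only bonds and modification states may differ
between the two sides.  Each rule is classified as ``bind``, ``unbind``,
``modify`` or ``modify-propagate`` from that difference.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace

__all__ = [
    "UNBOUND",
    "BOUND_ANY",
    "WILD",
    "MoleculeTypeDef",
    "SitePattern",
    "MoleculePattern",
    "ComplexPattern",
    "RuleDef",
    "ModelDef",
    "ModelError",
    "ParseError",
    "parse_model",
    "read_interaction_table",
    "model_from_interactions",
]

# Sentinel bond states for site patterns.
UNBOUND = "unbound"
BOUND_ANY = "bound-any"
WILD = "unspecified"


class ModelError(ValueError):
    """Semantic error in a model definition."""


class ParseError(ModelError):
    """Syntax error in model text; carries line/column information."""

    def __init__(self, message: str, line: int | None = None, col: int | None = None):
        loc = "" if line is None else f" (line {line}" + ("" if col is None else f", col {col}") + ")"
        super().__init__(message + loc)
        self.line = line
        self.col = col


@dataclass(frozen=True)
class MoleculeTypeDef:
    """An elementary molecule type: a name plus an ordered list of sites.

    Duplicate site names are allowed ("generic" sites) and are interchangeable
    for matching.  ``mod_states`` maps a site name to the tuple of allowed
    modification labels (empty tuple: the site carries no modification).
    """

    name: str
    sites: tuple[str, ...] = ()
    mod_states: dict = field(default_factory=dict)

    def site_slots(self, site_name: str) -> list[int]:
        return [i for i, s in enumerate(self.sites) if s == site_name]


@dataclass(frozen=True)
class SitePattern:
    site_name: str
    bond: object = UNBOUND  # UNBOUND | BOUND_ANY | WILD | int bond label
    mod: str | None = None  # None = unspecified


@dataclass(frozen=True)
class MoleculePattern:
    type_name: str
    sites: tuple[SitePattern, ...] = ()


@dataclass(frozen=True)
class ComplexPattern:
    """A connected pattern over one or more molecules sharing bond labels."""

    molecules: tuple[MoleculePattern, ...]

    def __post_init__(self):
        self.validate()

    def bond_ends(self) -> dict:
        """Map bond label -> list of (molecule index, site index) carrying it."""
        ends: dict = {}
        for mi, mol in enumerate(self.molecules):
            for si, sp in enumerate(mol.sites):
                if isinstance(sp.bond, int):
                    ends.setdefault(sp.bond, []).append((mi, si))
        return ends

    def validate(self):
        ends = self.bond_ends()
        for label, occ in ends.items():
            if len(occ) != 2:
                raise ModelError(f"bond label !{label} used {len(occ)} times (must be exactly 2)")
        if len(self.molecules) > 1:
            # connectivity over declared bonds
            adj: dict = {i: set() for i in range(len(self.molecules))}
            for (a, _), (b, _) in (tuple(v) for v in ends.values()):
                adj[a].add(b)
                adj[b].add(a)
            seen = {0}
            stack = [0]
            while stack:
                for j in adj[stack.pop()]:
                    if j not in seen:
                        seen.add(j)
                        stack.append(j)
            if len(seen) != len(self.molecules):
                raise ModelError("complex pattern is not connected by its bonds")


@dataclass
class RuleDef:
    """A unidirectional reaction rule.

    ``rate`` is a first-order rate constant (per unit time) for unimolecular
    rules, or a per-encounter binding probability for bimolecular rules.
    ``switch`` optionally names a binary switch gating the rule.
    """

    name: str
    lhs: tuple[ComplexPattern, ...]
    rhs: tuple[ComplexPattern, ...]
    rate: float = 1.0
    switch: str | None = None
    kind: str = field(init=False, default="")
    # actions, in flattened LHS molecule coordinates (gmol index, site index)
    bonds_formed: list = field(init=False, default_factory=list)
    bonds_broken: list = field(init=False, default_factory=list)
    mod_changes: list = field(init=False, default_factory=list)  # (gmol, site, new label)

    def __post_init__(self):
        self._derive_actions()

    @property
    def lhs_molecules(self) -> list[MoleculePattern]:
        return [m for cp in self.lhs for m in cp.molecules]

    @property
    def rhs_molecules(self) -> list[MoleculePattern]:
        return [m for cp in self.rhs for m in cp.molecules]

    def _derive_actions(self):
        lmols, rmols = self.lhs_molecules, self.rhs_molecules
        if [m.type_name for m in lmols] != [m.type_name for m in rmols]:
            raise ModelError(
                f"rule {self.name!r} does not conserve molecules: "
                f"{[m.type_name for m in lmols]} -> {[m.type_name for m in rmols]}"
            )

        def side_info(cplxs, mols):
            # global molecule index -> per occurrence-of-name site alignment
            bonds = set()
            ends: dict = {}
            mods: dict = {}
            off = 0
            for cp in cplxs:
                for li, mol in enumerate(cp.molecules):
                    g = off + li
                    for si, sp in enumerate(mol.sites):
                        # align site occurrences by (name, occurrence count)
                        occ = sum(1 for t in mol.sites[:si] if t.site_name == sp.site_name)
                        key = (g, sp.site_name, occ)
                        if isinstance(sp.bond, int):
                            ends.setdefault(("b", cp, sp.bond) if False else (id(cp), sp.bond), []).append(key)
                        elif sp.bond is BOUND_ANY:
                            ends.setdefault(("any", key), []).append(key)
                        if sp.mod is not None:
                            mods[key] = sp.mod
                off += len(cp.molecules)
            for v in ends.values():
                if len(v) == 2:
                    bonds.add(frozenset(v))
            return bonds, mods

        lbonds, lmods = side_info(self.lhs, lmols)
        rbonds, rmods = side_info(self.rhs, rmols)
        # every RHS-mentioned site must correspond to an LHS-mentioned occurrence
        lhs_keys = set()
        for g, mol in enumerate(lmols):
            for si, sp in enumerate(mol.sites):
                occ = sum(1 for t in mol.sites[:si] if t.site_name == sp.site_name)
                lhs_keys.add((g, sp.site_name, occ))
        for g, mol in enumerate(rmols):
            for si, sp in enumerate(mol.sites):
                occ = sum(1 for t in mol.sites[:si] if t.site_name == sp.site_name)
                if (g, sp.site_name, occ) not in lhs_keys:
                    raise ModelError(
                        f"rule {self.name!r}: site {mol.type_name}.{sp.site_name} appears on the "
                        "right-hand side only (both sides must mention the same sites)"
                    )
        self.bonds_formed = sorted((tuple(sorted(b)) for b in rbonds - lbonds))
        self.bonds_broken = sorted((tuple(sorted(b)) for b in lbonds - rbonds))
        self.mod_changes = sorted(
            (key, new) for key, new in rmods.items() if lmods.get(key) != new
        )
        nb, nu, nm = len(self.bonds_formed), len(self.bonds_broken), len(self.mod_changes)
        if nb + nu == 0 and nm == 0:
            raise ModelError(f"rule {self.name!r} has no effect")
        if nb + nu > 1:
            raise ModelError(
                f"rule {self.name!r} changes more than one bond (not supported)"
            )
        if nb:
            self.kind = "bind"
        elif nu:
            self.kind = "unbind"
        elif len(lmols) > 1:
            self.kind = "modify-propagate"
        else:
            self.kind = "modify"

    @property
    def is_bimolecular(self) -> bool:
        return self.kind == "bind" and len(self.lhs) == 2


@dataclass
class ModelDef:
    """A validated model: molecule types, rules and rule-gating switches."""

    molecule_types: dict = field(default_factory=dict)  # name -> MoleculeTypeDef
    rules: list = field(default_factory=list)
    switches: dict = field(default_factory=dict)  # tag -> bool
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self):
        names = list(self.molecule_types)
        if len(set(names)) != len(names):
            raise ModelError("duplicate molecule type name")
        for rule in self.rules:
            for mol in rule.lhs_molecules + rule.rhs_molecules:
                mt = self.molecule_types.get(mol.type_name)
                if mt is None:
                    raise ModelError(f"rule {rule.name!r}: unknown molecule type {mol.type_name!r}")
                slots = list(mt.sites)
                for sp in mol.sites:
                    if sp.site_name not in slots:
                        raise ModelError(
                            f"rule {rule.name!r}: molecule {mol.type_name!r} has no free "
                            f"occurrence of site {sp.site_name!r}"
                        )
                    slots.remove(sp.site_name)
                    if sp.mod is not None and sp.mod not in mt.mod_states.get(sp.site_name, ()):
                        raise ModelError(
                            f"rule {rule.name!r}: site {mol.type_name}.{sp.site_name} has no "
                            f"modification state {sp.mod!r}"
                        )
            if rule.switch is not None:
                self.switches.setdefault(rule.switch, True)

    @property
    def mod_labels(self) -> list[str]:
        """All modification labels, in stable declaration order."""
        out: list[str] = []
        for mt in self.molecule_types.values():
            for labels in mt.mod_states.values():
                for lab in labels:
                    if lab not in out:
                        out.append(lab)
        return out


# ---------------------------------------------------------------------------
# Parser for the BNGL subset
# ---------------------------------------------------------------------------

_IDENT = r"[A-Za-z_][A-Za-z0-9_]*"
_MOL_RE = re.compile(rf"({_IDENT})\(([^()]*)\)")


def _parse_site_token(tok: str, line: int) -> SitePattern:
    m = re.fullmatch(rf"({_IDENT})((?:~{_IDENT})*)(!\d+|!\+|!\?)?", tok)
    if not m:
        raise ParseError(f"bad site specification {tok!r}", line)
    name, mods, bond = m.group(1), m.group(2), m.group(3)
    mod = mods[1:] if mods else None
    if mod and "~" in mod:
        raise ParseError(f"site {tok!r}: more than one modification state in a pattern", line)
    if bond is None:
        b: object = UNBOUND
    elif bond == "!+":
        b = BOUND_ANY
    elif bond == "!?":
        b = WILD
    else:
        b = int(bond[1:])
    return SitePattern(name, b, mod)


def _parse_complex(text: str, line: int) -> ComplexPattern:
    mols = []
    pos = 0
    text = text.strip()
    while pos < len(text):
        m = _MOL_RE.match(text, pos)
        if not m:
            raise ParseError(f"bad molecule pattern near {text[pos:]!r}", line, pos + 1)
        name, inner = m.group(1), m.group(2).strip()
        sites = tuple(
            _parse_site_token(t.strip(), line) for t in inner.split(",") if t.strip()
        ) if inner else ()
        mols.append(MoleculePattern(name, sites))
        pos = m.end()
        if pos < len(text):
            if text[pos] != ".":
                raise ParseError(f"expected '.' between molecules, got {text[pos]!r}", line, pos + 1)
            pos += 1
    if not mols:
        raise ParseError("empty complex pattern", line)
    try:
        return ComplexPattern(tuple(mols))
    except ModelError as e:
        raise ParseError(str(e), line) from e


def _split_side(text: str, line: int) -> tuple[ComplexPattern, ...]:
    return tuple(_parse_complex(part, line) for part in text.split("+"))


def parse_model(text: str) -> ModelDef:
    """Parse model source text (BNGL subset) into a validated :class:`ModelDef`.

    Recognized blocks: ``parameters``, ``molecule types``, ``reaction rules``
    (each ``begin <block> ... end <block>``).  Rules may carry an optional
    leading ``name:`` label and a trailing ``@switch`` tag.
    """
    params: dict = {}
    types: dict = {}
    rules: list = []
    block = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        low = " ".join(line.lower().split())
        if low.startswith("begin "):
            if block is not None:
                raise ParseError(f"nested block {line!r}", lineno)
            block = low[6:]
            if block not in ("parameters", "molecule types", "reaction rules"):
                raise ParseError(f"unknown block {block!r}", lineno)
            continue
        if low.startswith("end "):
            if block != low[4:]:
                raise ParseError(f"mismatched end {line!r}", lineno)
            block = None
            continue
        if block is None:
            raise ParseError(f"statement outside block: {line!r}", lineno)
        if block == "parameters":
            parts = line.split()
            if len(parts) != 2:
                raise ParseError("parameter lines are '<name> <value>'", lineno)
            try:
                params[parts[0]] = float(parts[1])
            except ValueError as e:
                raise ParseError(f"bad parameter value {parts[1]!r}", lineno) from e
        elif block == "molecule types":
            m = re.fullmatch(rf"({_IDENT})\(([^()]*)\)", line)
            if not m:
                raise ParseError(f"bad molecule type declaration {line!r}", lineno)
            name, inner = m.group(1), m.group(2).strip()
            if name in types:
                raise ParseError(f"duplicate molecule type {name!r}", lineno)
            site_names: list[str] = []
            mod_states: dict = {}
            if inner:
                for tok in inner.split(","):
                    tok = tok.strip()
                    sm = re.fullmatch(rf"({_IDENT})((?:~{_IDENT})*)", tok)
                    if not sm:
                        raise ParseError(f"bad site declaration {tok!r}", lineno)
                    site_names.append(sm.group(1))
                    if sm.group(2):
                        labels = tuple(sm.group(2)[1:].split("~"))
                        prev = mod_states.setdefault(sm.group(1), labels)
                        if prev != labels:
                            raise ParseError(
                                f"site {sm.group(1)!r} declared with different state lists", lineno
                            )
            types[name] = MoleculeTypeDef(name, tuple(site_names), mod_states)
        else:  # reaction rules
            name = f"r{len(rules) + 1}"
            m = re.match(rf"({_IDENT})\s*:\s*", line)
            if m:
                name, line = m.group(1), line[m.end():]
            switch = None
            m = re.search(r"@(" + _IDENT + r")\s*$", line)
            if m:
                switch, line = m.group(1), line[: m.start()].strip()
            if "->" not in line:
                raise ParseError("rule must contain '->'", lineno)
            lhs_text, rhs_text = line.split("->", 1)
            rhs_parts = rhs_text.split()
            rate = 1.0
            if rhs_parts and re.fullmatch(rf"{_IDENT}|[-+0-9.eE]+", rhs_parts[-1]) and "(" not in rhs_parts[-1]:
                tok = rhs_parts[-1]
                try:
                    rate = float(tok)
                    rhs_text = rhs_text.rsplit(tok, 1)[0]
                except ValueError:
                    if tok in params:
                        rate = params[tok]
                        rhs_text = rhs_text.rsplit(tok, 1)[0]
                    elif "(" not in tok:
                        raise ParseError(f"unknown rate parameter {tok!r}", lineno)
            try:
                rules.append(
                    RuleDef(name, _split_side(lhs_text, lineno), _split_side(rhs_text, lineno), rate, switch)
                )
            except ModelError as e:
                if isinstance(e, ParseError):
                    raise
                raise ParseError(str(e), lineno) from e
    if block is not None:
        raise ParseError(f"unterminated block {block!r}")
    try:
        return ModelDef(types, rules, parameters=params)
    except ModelError:
        raise


# ---------------------------------------------------------------------------
# Interaction-table reader (the "interactions" table of the three-table input)
# ---------------------------------------------------------------------------

def read_interaction_table(source) -> "pandas.DataFrame":
    """Read a tab-separated interaction table.

    Required columns: ``protein_A, protein_B, site_A, site_B, rate_tag``.
    An optional ``switch`` column gates the expanded rule on a binary switch.
    """
    import pandas as pd

    df = pd.read_csv(source, sep="\t", comment="#", dtype=str).fillna("")
    required = ["protein_A", "protein_B", "site_A", "site_B", "rate_tag"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ModelError(f"interaction table missing columns {missing}")
    return df


def model_from_interactions(df, parameters: dict | None = None) -> ModelDef:
    """Expand an interaction table into a model of one bind rule per row.

    Each protein receives one specific site per listed partner (sites are
    taken from the table); each row becomes the rule
    ``A(sA) + B(sB) -> A(sA!1).B(sB!1)``.
    """
    parameters = dict(parameters or {})
    sites: dict = {}
    for _, row in df.iterrows():
        sites.setdefault(row.protein_A, []).append(row.site_A)
        sites.setdefault(row.protein_B, []).append(row.site_B)
    types = {
        name: MoleculeTypeDef(name, tuple(dict.fromkeys(slist)))
        for name, slist in sites.items()
    }
    seen = set()
    rules = []
    for _, row in df.iterrows():
        key = frozenset([(row.protein_A, row.site_A), (row.protein_B, row.site_B)])
        if key in seen:  # symmetric partner listing deduplicated
            continue
        seen.add(key)
        rate = parameters.get(row.rate_tag, 1.0) if row.rate_tag else 1.0
        lhs = (
            ComplexPattern((MoleculePattern(row.protein_A, (SitePattern(row.site_A),)),)),
            ComplexPattern((MoleculePattern(row.protein_B, (SitePattern(row.site_B),)),)),
        )
        rhs = (
            ComplexPattern((
                MoleculePattern(row.protein_A, (SitePattern(row.site_A, 1),)),
                MoleculePattern(row.protein_B, (SitePattern(row.site_B, 1),)),
            )),
        )
        switch = row.get("switch", "") or None
        rules.append(RuleDef(f"{row.protein_A}-{row.protein_B}", lhs, rhs, rate, switch))
    return ModelDef(types, rules, parameters=parameters)
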