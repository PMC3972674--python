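"""Bond-event records: which bonds are formed or broken, and when."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BondEvent", "FORMED", "BROKEN"]

FORMED = "formed"
BROKEN = "broken"


@dataclass(frozen=True)
class BondEvent:
    """One formed or broken bond: time-step, rule, and the two (particle, site
    slot) endpoints.  Site slots index into the owner's type-level site list."""

    step: int
    rule: str
    a_particle: int
    a_site: int
    b_particle: int
    b_site: int
    action: str  # FORMED | BROKEN

    def key(self) -> frozenset:
        return frozenset([(self.a_particle, self.a_site), (self.b_particle, self.b_site)])
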