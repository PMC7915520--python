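"""Shared result containers for QTL effects and co-localized loci.

A :class:`QTLEffect` is one significant trait-level mapping result; a
:class:`QTLLocus` groups effects whose support intervals overlap on one
chromosome and carries the plasticity/strategy labels assigned by the
classification rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

#: dosage coding: -1 for the domesticated parent, +1 for the wild parent
P1 = "P1"
P2 = "P2"

#: derivative-set tags: observed trait, phenology-adjusted residual,
#: drought plasticity I (WL-on-WW residual), drought plasticity II
#: (WL on WW + heading residual)
SET_TAGS = ("obs", "df", "d", "ddf")


@dataclass
class QTLEffect:
    """A single significant QTL effect for one trait/derivative-set."""

    trait: str
    set_tag: str                      # one of SET_TAGS
    env: Optional[str]                # "WW"/"WL" for obs/df sets, None for d/ddf
    chrom: str
    pos_cM: float
    lod: float
    additive: float                   # half the homozygote-mean difference, + toward P2
    pev: float                        # model R^2 at the peak
    support: tuple[float, float]      # 1.5-LOD support interval (cM)
    itv: str = ""                     # parent contributing the increasing allele
    env_specificity: Optional[str] = None  # WL-specific / WW-specific / both
    pos_sd: Optional[float] = None    # bootstrap SD of the peak position
    additive_sd: Optional[float] = None
    model: str = "single"

    def __post_init__(self) -> None:
        if self.set_tag not in SET_TAGS:
            raise ValueError(f"unknown set tag {self.set_tag!r}")
        if not self.itv:
            self.itv = P2 if self.additive > 0 else P1
        lo, hi = self.support
        if not (lo <= self.pos_cM <= hi):
            raise ValueError("support interval must contain the peak")

    @property
    def label(self) -> str:
        """Human-readable effect name, e.g. ``dGY`` or ``obs-GY(WL)``."""
        prefix = "" if self.set_tag == "obs" else self.set_tag
        env = f"({self.env})" if self.env else ""
        return f"{prefix}{self.trait}{env}"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["support"] = list(self.support)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "QTLEffect":
        d = dict(d)
        d["support"] = tuple(d["support"])
        return cls(**d)


@dataclass
class QTLLocus:
    """Co-localized QTL effects on one chromosome with classification labels."""

    locus_id: str
    chrom: str
    members: list[QTLEffect] = field(default_factory=list)
    support: tuple[float, float] = (0.0, 0.0)   # union of member intervals
    phenology_label: Optional[str] = None       # non-plastic/plastic/associated/not-applicable
    drought_label: Optional[str] = None         # non-plastic/plastic
    strategies: set[str] = field(default_factory=set)

    @property
    def traits(self) -> set[str]:
        return {m.trait for m in self.members}

    @property
    def multi_trait(self) -> bool:
        return len(self.traits) >= 2

    @property
    def peak_member(self) -> QTLEffect:
        return max(self.members, key=lambda m: m.lod)

    def to_dict(self) -> dict:
        return {
            "locus_id": self.locus_id,
            "chrom": self.chrom,
            "support": list(self.support),
            "phenology_label": self.phenology_label,
            "drought_label": self.drought_label,
            "strategies": sorted(self.strategies),
            "multi_trait": self.multi_trait,
            "members": [m.to_dict() for m in self.members],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QTLLocus":
        return cls(
            locus_id=d["locus_id"],
            chrom=d["chrom"],
            members=[QTLEffect.from_dict(m) for m in d["members"]],
            support=tuple(d["support"]),
            phenology_label=d.get("phenology_label"),
            drought_label=d.get("drought_label"),
            strategies=set(d.get("strategies", [])),
        )
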