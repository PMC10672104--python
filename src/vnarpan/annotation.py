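"""VNAR domain annotation from framework anchor motifs.

A VNAR protein is delimited into its framework and diversity regions

    FR1 < CDR1 < FR2 < HV2 < FR3a < HV4 < FR3b < CDR3 < FR4

by matching one anchor pattern per framework segment, left to right.  The
diversity regions (CDR1, HV2, HV4, CDR3) are whatever lies between
consecutive framework matches.  CDR3 — the clone identifier throughout this
package — is the stretch strictly between the second canonical framework
cysteine (the final residue of the FR3b anchor) and the start of the FR4
anchor, an ``xGxGTxVTV``-family motif.

Anchor patterns are data, not code: they use plain regular-expression
character classes and can be retargeted to other elasmobranch frameworks via
JSON.  VNAR types are likewise assigned from a configurable, ordered rule
table over the noncanonical cysteines (every Cys other than the two matched
canonical framework cysteines) and the CDR3.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

REGION_NAMES = ("FR1", "CDR1", "FR2", "HV2", "FR3a", "HV4", "FR3b", "CDR3", "FR4")

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: The aromatic residue set used for CDR3 descriptors.  Ile is included by
#: convention of the analysis this package reproduces, although it is not
#: chemically aromatic; ``AROMATIC_CHEMICAL`` is the strict alternative.
AROMATIC_DEFAULT = frozenset("IYFW")
AROMATIC_CHEMICAL = frozenset("FYW")

#: Integer side-chain charges at neutral pH (His counted as 0).
CHARGE_DEFAULT: Mapping[str, int] = {"R": 1, "K": 1, "D": -1, "E": -1}


class NotVnarError(ValueError):
    """Raised when a protein lacks a required framework anchor."""


def _literal_residues(pattern: str) -> str:
    """Residues of a pattern outside character classes (for validation)."""
    return re.sub(r"\[[^\]]*\]", ".", pattern)


@dataclass(frozen=True)
class AnchorConfig:
    """Framework anchor patterns delimiting the VNAR diversity regions.

    ``fr1``/``fr2``/``fr3a`` anchor the full FR1/FR2/FR3a segments;
    ``cdr3_n_anchor`` is the FR3b segment and must end at the second
    canonical cysteine; ``cdr3_c_anchor`` is the FR4 start motif.
    """

    fr1: str
    fr2: str
    fr3a: str
    cdr3_n_anchor: str
    cdr3_c_anchor: str

    def __post_init__(self) -> None:
        for name, pat in self.patterns.items():
            if not pat:
                raise ValueError(f"anchor pattern {name!r} is empty")
        lit = _literal_residues(self.cdr3_n_anchor)
        if not self.cdr3_n_anchor.endswith("C") or lit.count("C") != 1:
            raise ValueError(
                "cdr3_n_anchor must contain exactly one literal Cys, at its final position"
            )

    @property
    def patterns(self) -> dict[str, str]:
        return {
            "FR1": self.fr1,
            "FR2": self.fr2,
            "FR3a": self.fr3a,
            "FR3b": self.cdr3_n_anchor,
            "FR4": self.cdr3_c_anchor,
        }

    @property
    def fr_anchor_patterns(self) -> tuple[tuple[str, tuple[str, str]], ...]:
        """(region, (left anchor, right anchor)) for each diversity region."""
        return (
            ("CDR1", (self.fr1, self.fr2)),
            ("HV2", (self.fr2, self.fr3a)),
            ("HV4", (self.fr3a, self.cdr3_n_anchor)),
            ("CDR3", (self.cdr3_n_anchor, self.cdr3_c_anchor)),
        )

    def compiled(self) -> dict[str, re.Pattern[bytes]]:
        """Byte-level compiled patterns (cached on first use)."""
        cache = getattr(self, "_compiled", None)
        if cache is None:
            cache = {name: re.compile(pat.encode()) for name, pat in self.patterns.items()}
            object.__setattr__(self, "_compiled", cache)
        return cache

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "fr1": self.fr1,
                    "fr2": self.fr2,
                    "fr3a": self.fr3a,
                    "cdr3_n_anchor": self.cdr3_n_anchor,
                    "cdr3_c_anchor": self.cdr3_c_anchor,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "AnchorConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


#: Default anchors for the topeshark-style framework used by the simulator.
DEFAULT_ANCHORS = AnchorConfig(
    fr1="ARVDQTP[QR]TITKETGESLTINCVL[RK]D",
    fr2="TYWYRK[KC]SGSTNEESISKGG",
    fr3a="KSFSLRINDLT[VA]",
    cdr3_n_anchor="EDSGTYYC",
    cdr3_c_anchor="[DE]GAGT[AK]VTV[NC]",
)


@dataclass
class VnarDomain:
    """An annotated VNAR protein.

    ``regions`` maps each region name to a 0-based half-open interval in the
    protein's own sequential coordinates; reports render positions 1-based
    from the FR1 start.
    """

    protein: str
    regions: dict[str, tuple[int, int]]
    cdr3: str
    vnar_type: str = "unknown"
    noncanonical_cys: tuple[tuple[str, int], ...] = ()
    warnings: tuple[str, ...] = ()

    def region_seq(self, name: str) -> str:
        start, end = self.regions[name]
        return self.protein[start:end]

    @property
    def span(self) -> tuple[int, int]:
        return self.regions["FR1"][0], self.regions["FR4"][1]


@dataclass(frozen=True)
class Cdr3Descriptors:
    length: int
    net_charge: int
    aromatic_count: int
    cys_count: int


@dataclass(frozen=True)
class TypeRule:
    """One row of the VNAR type rule table.

    A rule matches when every listed region holds at least one noncanonical
    Cys (``cys_in``), none of the ``cys_not_in`` regions holds any, the CDR3
    cysteine count satisfies ``cdr3_cys`` (``"even"``, ``"==n"`` or
    ``">=n"``), and — when requested — a Trp is adjacent to the (first)
    noncanonical CDR1 cysteine.  ``no_noncanonical`` matches only domains
    with no noncanonical cysteines at all.
    """

    label: str
    cys_in: tuple[str, ...] = ()
    cys_not_in: tuple[str, ...] = ()
    cdr3_cys: str | None = None
    trp_adjacent_cdr1_cys: bool | None = None
    no_noncanonical: bool = False

    def matches(self, domain: VnarDomain) -> bool:
        regions_with = {region for region, _ in domain.noncanonical_cys}
        if self.no_noncanonical:
            return not domain.noncanonical_cys
        if any(r not in regions_with for r in self.cys_in):
            return False
        if any(r in regions_with for r in self.cys_not_in):
            return False
        if self.cdr3_cys is not None:
            n = domain.cdr3.count("C")
            spec = self.cdr3_cys
            if spec == "even":
                ok = n % 2 == 0
            elif spec.startswith(">="):
                ok = n >= int(spec[2:])
            elif spec.startswith("=="):
                ok = n == int(spec[2:])
            else:
                raise ValueError(f"bad cdr3_cys spec {spec!r}")
            if not ok:
                return False
        if self.trp_adjacent_cdr1_cys is not None:
            positions = [p for region, p in domain.noncanonical_cys if region == "CDR1"]
            adjacent = False
            for p in positions:
                left = domain.protein[p - 1] if p > 0 else ""
                right = domain.protein[p + 1] if p + 1 < len(domain.protein) else ""
                if "W" in (left, right):
                    adjacent = True
                    break
            if adjacent != self.trp_adjacent_cdr1_cys:
                return False
        return True


# Ordered first-match-wins table.  Type III (the Trp-refined variant of II)
# precedes II so that it is reachable.
DEFAULT_TYPE_RULES: tuple[TypeRule, ...] = (
    TypeRule("I", cys_in=("FR2", "FR4"), cdr3_cys="even"),
    TypeRule("III", cys_in=("CDR1",), cdr3_cys="==1", trp_adjacent_cdr1_cys=True),
    TypeRule("II", cys_in=("CDR1",), cdr3_cys="==1"),
    TypeRule("V", cdr3_cys=">=2", cys_not_in=("CDR1",)),
    TypeRule("IV", no_noncanonical=True),
)


def type_rules_from_json(path) -> tuple[TypeRule, ...]:
    with open(path) as fh:
        rows = json.load(fh)
    return tuple(
        TypeRule(
            label=row["label"],
            cys_in=tuple(row.get("cys_in", ())),
            cys_not_in=tuple(row.get("cys_not_in", ())),
            cdr3_cys=row.get("cdr3_cys"),
            trp_adjacent_cdr1_cys=row.get("trp_adjacent_cdr1_cys"),
            no_noncanonical=row.get("no_noncanonical", False),
        )
        for row in rows
    )


def _search_anchors(protein: bytes, anchors: AnchorConfig):
    """Match the five framework anchors left to right; leftmost wins."""
    compiled = anchors.compiled()
    matches: dict[str, re.Match[bytes]] = {}
    warnings: list[str] = []
    pos = 0
    for name in ("FR1", "FR2", "FR3a", "FR3b", "FR4"):
        m = compiled[name].search(protein, pos)
        if m is None:
            raise NotVnarError(f"anchor {name} not found")
        if compiled[name].search(protein, m.end()) is not None:
            warnings.append(f"multiple matches for anchor {name}; leftmost used")
        matches[name] = m
        pos = m.end()
    return matches, tuple(warnings)


def annotate(
    protein: str,
    anchors: AnchorConfig = DEFAULT_ANCHORS,
    type_rules: Sequence[TypeRule] = DEFAULT_TYPE_RULES,
) -> VnarDomain:
    """Delimit a VNAR protein into regions and classify its type.

    Raises :class:`NotVnarError` if any framework anchor is absent.
    """
    if not protein:
        raise ValueError("protein is empty")
    raw = protein.encode("ascii")
    matches, warns = _search_anchors(raw, anchors)
    m = {k: (v.start(), v.end()) for k, v in matches.items()}
    regions = {
        "FR1": m["FR1"],
        "CDR1": (m["FR1"][1], m["FR2"][0]),
        "FR2": m["FR2"],
        "HV2": (m["FR2"][1], m["FR3a"][0]),
        "FR3a": m["FR3a"],
        "HV4": (m["FR3a"][1], m["FR3b"][0]),
        "FR3b": m["FR3b"],
        "CDR3": (m["FR3b"][1], m["FR4"][0]),
        "FR4": m["FR4"],
    }
    cdr3 = protein[regions["CDR3"][0] : regions["CDR3"][1]]

    # canonical cysteines: the FR1 framework Cys and the FR3b terminal Cys
    fr1_start, fr1_end = regions["FR1"]
    canonical = {m["FR3b"][1] - 1}
    fr1_cys = protein.find("C", fr1_start, fr1_end)
    if fr1_cys != -1:
        canonical.add(fr1_cys)
    span_start, span_end = regions["FR1"][0], regions["FR4"][1]
    noncanon = []
    for pos in range(span_start, span_end):
        if protein[pos] == "C" and pos not in canonical:
            for region in REGION_NAMES:
                start, end = regions[region]
                if start <= pos < end:
                    noncanon.append((region, pos))
                    break
    domain = VnarDomain(
        protein=protein,
        regions=regions,
        cdr3=cdr3,
        noncanonical_cys=tuple(noncanon),
        warnings=warns,
    )
    domain.vnar_type = classify_type(domain, type_rules)
    return domain


def classify_type(
    domain: VnarDomain, rules: Sequence[TypeRule] = DEFAULT_TYPE_RULES
) -> str:
    """Assign a VNAR type by first-match-wins over the rule table."""
    for rule in rules:
        if rule.matches(domain):
            return rule.label
    return "unknown"


def extract_cdr3(protein: bytes | str, anchors: AnchorConfig = DEFAULT_ANCHORS) -> str | None:
    """Fast CDR3 extraction from the two CDR3 anchors alone.

    Returns None when either anchor is missing.  This is the hot path used
    for building abundance tables; :func:`annotate` adds the full region map
    and type call for reporting.
    """
    raw = protein.encode("ascii") if isinstance(protein, str) else protein
    compiled = anchors.compiled()
    m = compiled["FR3b"].search(raw)
    if m is None:
        return None
    m2 = compiled["FR4"].search(raw, m.end())
    if m2 is None:
        return None
    return raw[m.end() : m2.start()].decode("ascii")


def cdr3_descriptors(
    cdr3: str,
    aromatic_set: frozenset[str] | set[str] = AROMATIC_DEFAULT,
    charge_map: Mapping[str, int] = CHARGE_DEFAULT,
) -> Cdr3Descriptors:
    """Length, net charge, aromatic count and Cys count of a CDR3."""
    unknown = set(cdr3) - STANDARD_AA
    if unknown:
        raise ValueError(f"unknown residue letters {sorted(unknown)}")
    return Cdr3Descriptors(
        length=len(cdr3),
        net_charge=sum(charge_map.get(aa, 0) for aa in cdr3),
        aromatic_count=sum(aa in aromatic_set for aa in cdr3),
        cys_count=cdr3.count("C"),
    )


def residue_differences(a: str, b: str) -> int | None:
    """Hamming distance between equal-length CDR3s; None if non-comparable."""
    if len(a) != len(b):
        return None
    return sum(x != y for x, y in zip(a, b))
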