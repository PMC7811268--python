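"""Glycerolipid shorthand nomenclature.

Lipidomics platforms report glycerolipid species in a compact shorthand:
a class token followed by the total acyl-carbon and double-bond counts,
optionally with the individual acyl chains resolved, e.g. ``TAG 52:3``,
``PC(34:1)`` or ``MGDG36:6(18:3/18:3)``. Different exports disagree on
whitespace, parentheses and a handful of class synonyms (``TG`` for ``TAG``),
so this module normalizes all of those dialects into one structured model,
:class:`LipidSpecies`, and classifies each species into the four glycerolipid
categories used throughout the pipeline: neutral storage lipids (TAG/DAG/MAG),
galactolipids (MGDG/DGDG), phospholipids and betaine lipids (DGTS).

Ether and oxidized lipid notations (``O-``, ``P-``) are deliberately rejected:
the pipeline targets diacyl/triacyl glycerolipid panels that contain none.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import InconsistentChains, MalformedSpecies, UnknownLipidClass

__all__ = [
    "AcylChain",
    "LipidSpecies",
    "CLASS_VOCABULARY",
    "CLASS_SYNONYMS",
    "CATEGORY_OF_CLASS",
    "CATEGORIES",
    "parse_species",
    "categorize",
    "is_membrane",
]

#: Controlled vocabulary of glycerolipid class tokens.
CLASS_VOCABULARY: tuple[str, ...] = (
    "TAG", "DAG", "MAG",            # neutral storage lipids
    "MGDG", "DGDG",                 # galactolipids
    "PC", "PI", "PE", "PG", "PS", "CL", "PA", "LPE",  # phospholipids
    "DGTS",                         # betaine lipid
)

#: Synonyms applied (case-insensitively) before the vocabulary check.
CLASS_SYNONYMS: dict[str, str] = {
    "TG": "TAG",
    "DG": "DAG",
    "MG": "MAG",
    "LYSOPE": "LPE",
}

CATEGORIES: tuple[str, ...] = ("neutral", "galactolipid", "phospholipid", "betaine")

#: Fixed class -> category mapping.
CATEGORY_OF_CLASS: dict[str, str] = {
    "TAG": "neutral", "DAG": "neutral", "MAG": "neutral",
    "MGDG": "galactolipid", "DGDG": "galactolipid",
    "PC": "phospholipid", "PI": "phospholipid", "PE": "phospholipid",
    "PG": "phospholipid", "PS": "phospholipid", "CL": "phospholipid",
    "PA": "phospholipid", "LPE": "phospholipid",
    "DGTS": "betaine",
}


@dataclass(frozen=True, order=True)
class AcylChain:
    """One fatty-acyl chain, ``carbons:double_bonds`` (e.g. 18:3)."""

    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise MalformedSpecies(f"acyl chain needs >= 2 carbons, got {self.carbons}")
        if not 0 <= self.double_bonds < self.carbons:
            raise MalformedSpecies(
                f"chain {self.carbons}:{self.double_bonds}: double bonds must be "
                f"in [0, carbons)"
            )

    def __str__(self) -> str:  # "18:3"
        return f"{self.carbons}:{self.double_bonds}"


@dataclass(frozen=True)
class LipidSpecies:
    """A glycerolipid molecular species.

    Equality ignores ``raw_name`` so that the same species parsed from
    different shorthand dialects compares equal.
    """

    lipid_class: str
    total_carbons: int
    total_double_bonds: int
    chains: tuple[AcylChain, ...] | None = None
    raw_name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.lipid_class not in CATEGORY_OF_CLASS:
            raise UnknownLipidClass(f"unknown lipid class {self.lipid_class!r}")
        if self.total_carbons <= 0:
            raise MalformedSpecies("total_carbons must be positive")
        if self.total_double_bonds < 0:
            raise MalformedSpecies("total_double_bonds must be >= 0")
        if self.chains is not None:
            c = sum(ch.carbons for ch in self.chains)
            d = sum(ch.double_bonds for ch in self.chains)
            if (c, d) != (self.total_carbons, self.total_double_bonds):
                raise InconsistentChains(
                    f"{self.raw_name or self.lipid_class}: chains sum to {c}:{d}, "
                    f"totals say {self.total_carbons}:{self.total_double_bonds}"
                )

    @property
    def category(self) -> str:
        return CATEGORY_OF_CLASS[self.lipid_class]

    def canonical(self) -> str:
        """Canonical text form, ``CLASS C:D`` or ``CLASS C:D(a:b/...)``."""
        base = f"{self.lipid_class} {self.total_carbons}:{self.total_double_bonds}"
        if self.chains:
            return base + "(" + "/".join(str(ch) for ch in self.chains) + ")"
        return base


_CLASS_RE = re.compile(r"^\s*([A-Za-z]+)")
_ETHER_RE = re.compile(r"\b[OP]-")
_BODY_RE = re.compile(
    r"""^(?P<open>\()?\s*
        (?P<carbons>\d+)\s*:\s*(?P<dbonds>\d+)
        \s*(?P<close>\))?\s*
        (?:\(\s*(?P<chains>\d+\s*:\s*\d+(?:\s*/\s*\d+\s*:\s*\d+)*)\s*\))?
        \s*$""",
    re.VERBOSE,
)


def parse_species(name: str) -> LipidSpecies:
    """Parse a shorthand species name into a :class:`LipidSpecies`.

    Accepts the dialects ``TAG 52:3``, ``TAG52:3`` and ``TAG(52:3)``, each with
    an optional resolved-chain annotation such as ``(18:3/18:3)``.

    Raises
    ------
    UnknownLipidClass
        The class token is not in the vocabulary (after synonym mapping).
    MalformedSpecies
        The ``carbons:double_bonds`` block is absent or garbled, or an
        ether/oxidized notation (``O-``/``P-``) is present.
    InconsistentChains
        Resolved chains do not sum to the stated totals.
    """
    if not name or not name.strip():
        raise MalformedSpecies("empty species name")
    m = _CLASS_RE.match(name)
    if m is None:
        raise MalformedSpecies(f"cannot read class token in {name!r}")
    token = m.group(1)
    lipid_class = CLASS_SYNONYMS.get(token.upper(), token.upper())
    rest = name[m.end():].strip()
    if _ETHER_RE.search(rest):
        raise MalformedSpecies(f"ether/oxidized notation not supported: {name!r}")
    body = _BODY_RE.match(rest)
    if body is None:
        raise MalformedSpecies(f"malformed carbon:double-bond block in {name!r}")
    if bool(body.group("open")) != bool(body.group("close")):
        raise MalformedSpecies(f"unbalanced parentheses in {name!r}")
    if lipid_class not in CATEGORY_OF_CLASS:
        raise UnknownLipidClass(f"unknown lipid class {token!r} in {name!r}")
    chains: tuple[AcylChain, ...] | None = None
    if body.group("chains"):
        parts = re.split(r"\s*/\s*", body.group("chains"))
        chains = tuple(
            AcylChain(*(int(x) for x in p.split(":"))) for p in parts
        )
    return LipidSpecies(
        lipid_class=lipid_class,
        total_carbons=int(body.group("carbons")),
        total_double_bonds=int(body.group("dbonds")),
        chains=chains,
        raw_name=name,
    )


def categorize(species: LipidSpecies | str) -> str:
    """Category of a species (or bare class token): neutral, galactolipid,
    phospholipid or betaine."""
    cls = species.lipid_class if isinstance(species, LipidSpecies) else species
    try:
        return CATEGORY_OF_CLASS[cls]
    except KeyError:
        raise UnknownLipidClass(f"unknown lipid class {cls!r}") from None


def is_membrane(species: LipidSpecies | str) -> bool:
    """Membrane-lipid predicate: every category except neutral storage."""
    return categorize(species) != "neutral"
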