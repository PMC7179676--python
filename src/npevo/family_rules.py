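"""Processing grammars of the 21 single-copy neuropeptide precursor families.

Polyneopteran single-copy precursors share a stereotyped architecture: a
signal peptide, an optional propeptide, exactly one bioactive peptide core
flanked by basic prohormone-convertase cleavage motifs (R, KR, RKR, RRRR,
...), and fast-evolving linker regions.  A :class:`FamilyRule` records, per
family, where the core sits in the precursor, which flank motifs delimit it,
and which post-translational modifications are expected (C-terminal amidation
via a Gly donor; N-terminal Gln cyclization to pyroglutamate).

The default registry (``data/family_rules.yaml``) covers the 21 families:
ACP, AST-CC, AST-CCC, AT, CCAP, CCHamide-1/2, CNMamide, corazonin, CRF-DH,
CT-DH, elevenin, HanSolin, MS, NPF-1/2, proctolin, RFLamide, SIFamide, sNPF
and trissin.  Adipokinetic-hormone precursors and multiple-copy families are
deliberately absent.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping

import yaml

AA20 = "ACDEFGHIKLMNPQRSTVWY"
BASIC_RESIDUES = "KR"

LOCATIONS = ("post_signal", "c_terminal", "internal", "post_propeptide")

#: Sentinel names usable in rule configs instead of a motif list.
SIGNAL_PEPTIDE = "signal_peptide"
PRECURSOR_END = "precursor_end"

FAMILY_IDS = (
    "ACP", "AST-CC", "AST-CCC", "AT", "CCAP", "CCHamide-1", "CCHamide-2",
    "CNMamide", "corazonin", "CRF-DH", "CT-DH", "elevenin", "HanSolin", "MS",
    "NPF-1", "NPF-2", "proctolin", "RFLamide", "SIFamide", "sNPF", "trissin",
)


class RuleValidationError(ValueError):
    """A rule config is malformed (bad motif, duplicate id, unknown location)."""


class UnknownFamilyError(KeyError):
    """Requested family is not in the registry (e.g. the excluded AKH)."""

    def __init__(self, family_id: str, valid: Iterable[str]):
        self.family_id = family_id
        self.valid = tuple(valid)
        super().__init__(
            f"unknown family {family_id!r}; valid ids: {', '.join(self.valid)}"
        )


def _check_motif(pattern: str, family: str = "?") -> str:
    if not pattern or len(pattern) > 4 or any(c not in BASIC_RESIDUES for c in pattern):
        raise RuleValidationError(
            f"family {family}: malformed cleavage motif {pattern!r} "
            "(must be 1-4 characters over K/R)"
        )
    return pattern


@dataclass(frozen=True)
class CleavageMotif:
    """A mono- to tetrabasic convertase recognition motif.

    ``side`` is ``"N-flank"`` or ``"C-flank"`` relative to the mature peptide.
    """

    pattern: str
    side: str

    def __post_init__(self):
        _check_motif(self.pattern)
        if self.side not in ("N-flank", "C-flank"):
            raise RuleValidationError(f"bad motif side {self.side!r}")

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class FamilyRule:
    """Excision grammar for one single-copy precursor family.

    ``n_flank`` / ``c_flank`` are motif alternates (order-specific variants);
    the scanner accepts any member.  An empty ``n_flank`` means the mature
    peptide directly follows the signal peptide; ``c_allows_precursor_end``
    means the peptide may run to the precursor C-terminus (AST-CC).
    """

    family_id: str
    location: str
    n_flank: tuple[str, ...]
    c_flank: tuple[str, ...]
    amidated: bool
    pglu_expected: bool = False
    retain_post_signal_basics: bool = False
    c_allows_precursor_end: bool = False
    expected_length: tuple[int, int] = (4, 200)
    secondary_site: int | None = None

    def __post_init__(self):
        if self.location not in LOCATIONS:
            raise RuleValidationError(
                f"family {self.family_id}: unknown location {self.location!r} "
                f"(one of {', '.join(LOCATIONS)})"
            )
        for pat in self.n_flank + self.c_flank:
            _check_motif(pat, self.family_id)
        if self.location != "post_signal" and not self.n_flank:
            raise RuleValidationError(
                f"family {self.family_id}: location {self.location} requires N-flank motifs"
            )
        if not self.c_flank and not self.c_allows_precursor_end:
            raise RuleValidationError(
                f"family {self.family_id}: no C-flank motifs and precursor_end not allowed"
            )
        lo, hi = self.expected_length
        if not (0 < lo <= hi):
            raise RuleValidationError(
                f"family {self.family_id}: bad expected_length {self.expected_length}"
            )

    @property
    def n_is_signal(self) -> bool:
        return not self.n_flank

    def n_motifs(self) -> tuple[CleavageMotif, ...]:
        return tuple(CleavageMotif(p, "N-flank") for p in self.n_flank)

    def c_motifs(self) -> tuple[CleavageMotif, ...]:
        return tuple(CleavageMotif(p, "C-flank") for p in self.c_flank)


@dataclass(frozen=True)
class ReferencePeptide:
    """A family's printed ancestral/consensus mature peptide and its outgroup evidence.

    ``sequence`` uses 'X' for positions without an assigned ancestral residue
    (trissin) or for the variable positions of a consensus (CRF-DH); such
    entries carry ``complete=False``.  For families whose full ancestral
    sequence could not be determined, ``sequence`` is the printed conserved
    C-terminal fragment and ``fragment=True``.
    """

    family_id: str
    sequence: str
    outgroup_hits: tuple[str, ...] = ()
    complete: bool = True
    fragment: bool = False
    ends_precursor: bool = False
    note: str = ""


#: Printed ancestral / consensus peptides per family, with the outgroup taxa
#: in which the identical sequence (or its diagnostic features) was reported.
REFERENCE_PEPTIDES: dict[str, ReferencePeptide] = {
    r.family_id: r
    for r in (
        ReferencePeptide("ACP", "QVTFSRDWNA", ("Remipedia",)),
        ReferencePeptide("AST-CC", "GQQKGRVYWRCYFNAVTCF", ("Zygentoma",),
                         ends_precursor=True),
        ReferencePeptide("AST-CCC", "SYWKQCAFNAVSCF", ("Remipedia",)),
        ReferencePeptide("AT", "GFKNVALSTARGF", ("Zygentoma",)),
        ReferencePeptide("CCAP", "PFCNAFTGC", ("Remipedia",)),
        ReferencePeptide("CCHamide-1", "GSCLSYGHSCWGAH", ("Zygentoma",)),
        ReferencePeptide("CCHamide-2", "KRGCSAFGHSCFGGH", ("Zygentoma",),
                         note="N-terminal KR retained in the mature peptide"),
        ReferencePeptide("CNMamide", "GSYMSLCHFKICNM", ("Zygentoma",)),
        ReferencePeptide("corazonin", "QTFQYSRGWTN", ("other",),
                         note="identical sequence in Malacostraca and Myriapoda"),
        ReferencePeptide("CRF-DH", "PSLSIVNXXDVLRQRXXLEXXRXRMR", (),
                         complete=False, fragment=True,
                         note="consensus; x = variable position"),
        ReferencePeptide("CT-DH", "GLDLGLSRGFSGSQAAKHLMGLAAANYAGGP",
                         ("Zygentoma",)),
        ReferencePeptide("elevenin", "CRGVAA", ("Zygentoma",), fragment=True,
                         note="conserved C-terminus; ancestral sequence undetermined"),
        ReferencePeptide("HanSolin", "GQPLRW", ("Zygentoma",), fragment=True,
                         note="conserved C-terminal hexapeptide"),
        ReferencePeptide("MS", "QDVDHVFLRF", ("Remipedia",)),
        ReferencePeptide("NPF-1", "LQELDRYYSQVARPRF", (), fragment=True,
                         note="fully conserved C-terminus"),
        ReferencePeptide("NPF-2", "RPRF", (), fragment=True,
                         note="fully conserved C-terminus"),
        ReferencePeptide("proctolin", "RYLPT", ("Remipedia", "other")),
        ReferencePeptide("RFLamide", "PASAIFTNIRFL", ()),
        ReferencePeptide("SIFamide", "TYRKPPFNGSIF", ()),
        ReferencePeptide("sNPF", "SNRSPSLRLRF", ("Zygentoma",)),
        ReferencePeptide("trissin", "LSCDSCGRECXXXCGTRNFRTCCFNYL",
                         ("Zygentoma",), complete=False,
                         note="XXX: no ancestral residues assigned"),
    )
}


def _rule_from_mapping(entry: Mapping) -> FamilyRule:
    try:
        fam = str(entry["id"])
    except (KeyError, TypeError):
        raise RuleValidationError(f"rule entry without an id: {entry!r}")
    n = entry.get("n_flank", SIGNAL_PEPTIDE)
    n_flank = () if n == SIGNAL_PEPTIDE else tuple(str(m) for m in n)
    c = entry.get("c_flank", [])
    if isinstance(c, str):
        c = [c]
    c_allows_end = PRECURSOR_END in c
    c_flank = tuple(str(m) for m in c if m != PRECURSOR_END)
    lr = entry.get("length_range", [4, 200])
    return FamilyRule(
        family_id=fam,
        location=str(entry.get("location", "")),
        n_flank=n_flank,
        c_flank=c_flank,
        amidated=bool(entry.get("amidated", False)),
        pglu_expected=bool(entry.get("pglu", False)),
        retain_post_signal_basics=bool(entry.get("retain_post_signal_basics", False)),
        c_allows_precursor_end=c_allows_end,
        expected_length=(int(lr[0]), int(lr[1])),
        secondary_site=entry.get("secondary_site"),
    )


def load_family_rules(config_source=None) -> list[FamilyRule]:
    """Parse and validate a rule-config document into a registry.

    ``config_source`` may be ``None`` (packaged default), a path to a YAML
    file, a YAML string, or an already-parsed mapping/list.  Raises
    :class:`RuleValidationError` naming the offending family on duplicate
    ids, unknown locations or malformed motifs.
    """
    if config_source is None:
        text = (
            importlib.resources.files("npevo.data")
            .joinpath("family_rules.yaml")
            .read_text()
        )
        doc = yaml.safe_load(text)
    elif isinstance(config_source, (list, dict)):
        doc = config_source
    else:
        p = Path(config_source)
        try:
            is_file = p.exists()
        except OSError:  # long YAML text is not a path
            is_file = False
        if is_file:
            doc = yaml.safe_load(p.read_text())
        else:
            doc = yaml.safe_load(str(config_source))
    entries = doc.get("families", doc) if isinstance(doc, dict) else doc
    if not isinstance(entries, list):
        raise RuleValidationError("rule config must hold a list of family mappings")
    rules = [_rule_from_mapping(e) for e in entries]
    seen: set[str] = set()
    for r in rules:
        key = r.family_id.lower()
        if key in seen:
            raise RuleValidationError(f"duplicate family_id {r.family_id!r}")
        seen.add(key)
    return rules


def dump_family_rules(registry: Iterable[FamilyRule]) -> str:
    """Serialize a registry back to the YAML config dialect (round-trips)."""
    out = []
    for r in registry:
        e: dict = {
            "id": r.family_id,
            "location": r.location,
            "n_flank": SIGNAL_PEPTIDE if r.n_is_signal else list(r.n_flank),
            "c_flank": list(r.c_flank)
            + ([PRECURSOR_END] if r.c_allows_precursor_end else []),
            "amidated": r.amidated,
            "pglu": r.pglu_expected,
            "length_range": list(r.expected_length),
        }
        if r.retain_post_signal_basics:
            e["retain_post_signal_basics"] = True
        if r.secondary_site is not None:
            e["secondary_site"] = r.secondary_site
        out.append(e)
    return yaml.safe_dump({"families": out}, sort_keys=False)


def merge_registries(
    base: Iterable[FamilyRule], overrides: Iterable[FamilyRule]
) -> list[FamilyRule]:
    """Overlay user rules on a base registry, matching by family_id."""
    by_id = {r.family_id.lower(): r for r in base}
    for r in overrides:
        by_id[r.family_id.lower()] = r
    return list(by_id.values())


@lru_cache(maxsize=1)
def _default_registry() -> tuple[FamilyRule, ...]:
    return tuple(load_family_rules(None))


def default_registry() -> list[FamilyRule]:
    """The packaged 21-family registry."""
    return list(_default_registry())


def rule_for(family_id: str, registry: Iterable[FamilyRule] | None = None) -> FamilyRule:
    """Case-insensitive exact lookup of a family's rule."""
    rules = list(registry) if registry is not None else default_registry()
    for r in rules:
        if r.family_id.lower() == family_id.lower():
            return r
    raise UnknownFamilyError(family_id, (r.family_id for r in rules))
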