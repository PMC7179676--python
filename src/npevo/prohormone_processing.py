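"""Excision of mature neuropeptides from precursor sequences.

Given a precursor with a known signal-peptide boundary and its family's
grammar, the functions here locate the basic convertase cleavage motifs,
slice out the mature peptide core, and annotate the expected
post-translational modifications: C-terminal amidation (the core is followed
by the amide-donor Gly, which is excluded from the core) and N-terminal
pyroglutamate (core starts with Gln in a family where the conversion is
documented).

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .family_rules import (
    AA20,
    PRECURSOR_END,
    REFERENCE_PEPTIDES,
    SIGNAL_PEPTIDE,
    CleavageMotif,
    FamilyRule,
    default_registry,
    rule_for,
)

VALID_RESIDUES = frozenset(AA20) | {"X", "?"}

#: Crude default used by the fallback signal-boundary heuristic; real
#: boundaries should come from a predictor or the simulator's ground truth.
DEFAULT_SIGNAL_LENGTH = 20

MIN_CORE_LENGTH = 4


class ExcisionError(ValueError):
    """Base class for excision failures."""


class PeptideNotFoundError(ExcisionError):
    """No candidate segment satisfied the family grammar."""


class DegeneratePeptideError(ExcisionError):
    """All candidate segments were shorter than the minimum core length."""


@dataclass
class Precursor:
    """An annotated precursor amino-acid sequence.

    ``residues`` is a string over the 20 amino acids plus 'X' (gap/unknown)
    and '?' (unresolved); ``signal_end`` is the 0-based index of the first
    residue after the signal peptide; ``complete=False`` marks transcripts
    with unresolved positions.
    """

    id: str
    residues: str
    signal_end: int
    family_id: str | None = None
    species: str = ""
    order: str = ""
    complete: bool = True

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"{self.id}: empty precursor sequence")
        for i, c in enumerate(self.residues):
            if c not in VALID_RESIDUES:
                raise ValueError(f"{self.id}: illegal residue {c!r} at position {i}")
        if not (0 <= self.signal_end < len(self.residues)):
            raise ValueError(
                f"{self.id}: signal_end {self.signal_end} outside sequence "
                f"of length {len(self.residues)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CleavageSite:
    """A motif occurrence in precursor coordinates; ``residues[start:end] == motif``.

    Sentinel sites (``signal_peptide``, ``precursor_end``) have start == end.
    """

    start: int
    end: int
    motif: str


@dataclass(frozen=True)
class MaturePeptide:
    """An excised mature-peptide core with coordinates and PTM flags."""

    family_id: str
    core: str
    start: int
    end: int
    amidated: bool = False
    pglu: bool = False
    n_site: CleavageSite | None = None
    c_site: CleavageSite | None = None
    low_confidence: bool = False
    warnings: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.core)


def scan_cleavage_sites(
    precursor: Precursor,
    motifs: Iterable[CleavageMotif | str],
    start: int | None = None,
) -> list[CleavageSite]:
    """All non-overlapping matches of a motif set, left to right.

    Longest-match precedence applies at each locus.  Sites inside the signal
    peptide are excluded (scanning begins at ``signal_end`` unless ``start``
    overrides it).
    """
    patterns = sorted(
        {m.pattern if isinstance(m, CleavageMotif) else str(m) for m in motifs},
        key=len,
        reverse=True,
    )
    seq = precursor.residues
    i = precursor.signal_end if start is None else start
    sites: list[CleavageSite] = []
    while i < len(seq):
        for pat in patterns:
            if seq.startswith(pat, i):
                sites.append(CleavageSite(i, i + len(pat), pat))
                i += len(pat)
                break
        else:
            i += 1
    return sites


@dataclass(frozen=True)
class _Candidate:
    start: int
    end: int  # core end, amide-donor Gly already excluded
    amide_g: bool
    n_site: CleavageSite
    c_site: CleavageSite


def _make_candidate(
    seq: str, core_start: int, n_site: CleavageSite, c_site: CleavageSite | None, rule: FamilyRule
) -> _Candidate:
    seg_end = c_site.start if c_site is not None else len(seq)
    amide_g = rule.amidated and seg_end - 1 > core_start and seq[seg_end - 1] == "G"
    core_end = seg_end - 1 if amide_g else seg_end
    if c_site is None:
        c_site = CleavageSite(len(seq), len(seq), PRECURSOR_END)
    return _Candidate(core_start, core_end, amide_g, n_site, c_site)


def _basic_runs(seq: str, start: int) -> list[tuple[int, int]]:
    """Maximal runs of K/R downstream of ``start``, as half-open spans."""
    runs = []
    i = start
    n = len(seq)
    while i < n:
        if seq[i] in "KR":
            j = i
            while j < n and seq[j] in "KR":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _classified_sites(
    precursor: Precursor, rule: FamilyRule
) -> tuple[list[CleavageSite], list[CleavageSite]]:
    """Flank sites anchored on maximal basic runs.

    Convertases recognize runs of basic residues, so motifs are matched
    against whole runs rather than greedily along the sequence: an N-flank
    motif at its rightmost occurrence within a run (the core starts right
    after it) and a C-flank motif at its leftmost occurrence (the core ends
    where it starts).  This keeps site assignment stable when a run is
    extended by a neighboring substitution (the KR inside KKR or KRK is
    still an N-flank) and stops short motifs of one set from matching inside
    longer runs that belong to the other.
    """
    seq = precursor.residues
    n_sites: list[CleavageSite] = []
    c_sites: list[CleavageSite] = []
    for i, j in _basic_runs(seq, precursor.signal_end):
        run = seq[i:j]
        best_n = None  # rightmost occurrence; longer motif wins ties
        for m in rule.n_flank:
            pos = run.rfind(m)
            if pos >= 0:
                key = (pos + len(m), len(m))
                if best_n is None or key > best_n[0]:
                    best_n = (key, m, pos)
        if best_n is not None:
            _, m, pos = best_n
            n_sites.append(CleavageSite(i + pos, i + pos + len(m), m))
        best_c = None  # leftmost occurrence; longer motif wins ties
        for m in rule.c_flank:
            pos = run.find(m)
            if pos >= 0:
                key = (pos, -len(m))
                if best_c is None or key < best_c[0]:
                    best_c = (key, m, pos)
        if best_c is not None:
            _, m, pos = best_c
            c_sites.append(CleavageSite(i + pos, i + pos + len(m), m))
    return n_sites, c_sites


def excise_mature_peptide(precursor: Precursor, rule: FamilyRule) -> MaturePeptide:
    """Locate and slice out the mature peptide core per the family grammar.

    Core placement by ``rule.location``:

    * ``post_signal`` — from ``signal_end`` to the nearest downstream C-flank
      site (a flank motif at ``signal_end`` itself is kept inside the core
      when ``retain_post_signal_basics``);
    * ``c_terminal`` — from the last workable N-flank site to the following
      C-flank site or, where allowed, the precursor end;
    * ``internal`` / ``post_propeptide`` — between the nearest N-flank /
      C-flank pair downstream of the signal peptide.

    When several segments satisfy the grammar, candidates are ranked by the
    strength of their supporting evidence: presence of the amide-donor Gly
    (for amidated families) first, agreement with the family's advisory
    length range second, position preference last.  A basic residue inside
    the peptide that happens to match a listed flank motif therefore does
    not truncate the core.  Deterministic: identical input yields identical
    output.
    """
    if rule.family_id and precursor.family_id and (
        rule.family_id.lower() != precursor.family_id.lower()
    ):
        raise ValueError(
            f"{precursor.id}: precursor family {precursor.family_id!r} does not "
            f"match rule {rule.family_id!r}"
        )
    seq = precursor.residues
    s0 = precursor.signal_end
    warnings: list[str] = []
    low_confidence = False

    n_sites, c_sites = _classified_sites(precursor, rule)
    if rule.retain_post_signal_basics:
        c_sites = [cs for cs in c_sites if cs.start != s0]

    signal_sentinel = CleavageSite(s0, s0, SIGNAL_PEPTIDE)
    fallback_starts: list[tuple[int, CleavageSite]] = []
    if rule.location == "post_signal":
        starts: list[tuple[int, CleavageSite]] = [(s0, signal_sentinel)]
    else:
        if not n_sites and rule.location != "internal":
            raise PeptideNotFoundError(
                f"{precursor.id} ({rule.family_id}): no N-flank site "
                f"matching {rule.n_flank} downstream of the signal peptide"
            )
        if rule.location == "c_terminal":
            starts = [(ns.end, ns) for ns in reversed(n_sites)]
        else:  # internal, post_propeptide: nearest first
            starts = [(ns.end, ns) for ns in n_sites]
        if rule.location == "internal":
            # e.g. earwig CRF-DH precursors lacking the N-flank motif: fall
            # back to the C-flank-terminated segment from the signal boundary
            fallback_starts = [(s0, signal_sentinel)]

    candidates: list[_Candidate] = []
    n_regular = 0
    for core_start, n_site in starts + fallback_starts:
        for cs in c_sites:
            if cs.start >= core_start:
                candidates.append(_make_candidate(seq, core_start, n_site, cs, rule))
        if rule.c_allows_precursor_end:
            candidates.append(_make_candidate(seq, core_start, n_site, None, rule))
        if (core_start, n_site) in starts:
            n_regular = len(candidates)

    lo, hi = rule.expected_length

    def _tier(c: _Candidate) -> int:
        amide_ok = (not rule.amidated) or c.amide_g
        in_range = lo <= c.end - c.start <= hi
        return (0 if amide_ok else 2) + (0 if in_range else 1)

    viable = [
        (i, c) for i, c in enumerate(candidates)
        if c.end - c.start >= MIN_CORE_LENGTH
    ]
    # fallback-start candidates only compete when no regular start works
    regular = [(i, c) for i, c in viable if i < n_regular]
    pool = regular or viable
    pick = min(pool, key=lambda ic: (_tier(ic[1]), ic[0]))[1] if pool else None
    if pick is not None and not regular and fallback_starts:
        low_confidence = True
        warnings.append("no workable N-flank site; segment taken from signal boundary")
    if pick is not None and rule.amidated and not pick.amide_g:
        warnings.append("amide signal missing")
    if pick is None:
        if candidates:
            raise DegeneratePeptideError(
                f"{precursor.id} ({rule.family_id}): all candidate segments "
                f"shorter than {MIN_CORE_LENGTH} residues"
            )
        raise PeptideNotFoundError(
            f"{precursor.id} ({rule.family_id}): no C-flank site matching "
            f"{rule.c_flank} downstream of the core start"
        )

    core = seq[pick.start : pick.end]
    lo, hi = rule.expected_length
    if not (lo <= len(core) <= hi):
        warnings.append(
            f"core length {len(core)} outside advisory range {lo}-{hi}"
        )
    if precursor.complete and any(c in core for c in "X?"):
        warnings.append("unresolved residues in core of a precursor flagged complete")
    if rule.secondary_site is not None and len(core) >= rule.secondary_site:
        res = core[rule.secondary_site - 1]
        if res in "KR":
            warnings.append(
                f"potential secondary cleavage site ({res}{rule.secondary_site}); not applied"
            )
    return MaturePeptide(
        family_id=rule.family_id,
        core=core,
        start=pick.start,
        end=pick.end,
        n_site=pick.n_site,
        c_site=pick.c_site,
        low_confidence=low_confidence,
        warnings=tuple(warnings),
    )


def annotate_ptms(
    peptide: MaturePeptide, precursor: Precursor, rule: FamilyRule
) -> MaturePeptide:
    """Write amidation and pyroglutamate flags onto the excised peptide.

    ``amidated`` is true iff the residue immediately after the core and
    before the C-flank motif is the amide-donor Gly; ``pglu`` is true iff the
    core starts with Gln and the family documents the conversion.
    """
    seq = precursor.residues
    c_start = peptide.c_site.start if peptide.c_site is not None else len(seq)
    amidated = peptide.end < c_start and peptide.end < len(seq) and seq[peptide.end] == "G"
    warnings = peptide.warnings
    if rule.amidated and not amidated and "amide signal missing" not in warnings:
        warnings = warnings + ("amide signal missing",)
    pglu = rule.pglu_expected and peptide.core.startswith("Q")
    return replace(peptide, amidated=amidated, pglu=pglu, warnings=warnings)


def process_precursor(
    precursor: Precursor, rule: FamilyRule | None = None
) -> MaturePeptide:
    """Excise and PTM-annotate in one step (rule looked up from the precursor)."""
    if rule is None:
        if precursor.family_id is None:
            raise ValueError(f"{precursor.id}: no family_id and no rule given")
        rule = rule_for(precursor.family_id)
    return annotate_ptms(excise_mature_peptide(precursor, rule), precursor, rule)


def crude_signal_end(residues: str, default_length: int = DEFAULT_SIGNAL_LENGTH) -> int:
    """Approximate fallback signal boundary: a fixed prefix length, clipped.

    This is deliberately crude; use a dedicated predictor (or simulator
    ground truth) whenever possible.
    """
    return min(default_length, max(1, len(residues) - 1))


# ---------------------------------------------------------------------------
# Reference fixtures: precursors assembled around each family's printed
# ancestral/consensus peptide, used by tests and as simulator scaffolds.
# ---------------------------------------------------------------------------

#: Generic 20-residue synthetic signal peptide (hydrophobic core, no Gly/basic
#: residues near the boundary).
SYNTHETIC_SIGNAL = "MKTFLVLAVLCLSAAFVSEA"

_LINKER_ALPHABET = "ADESTNQLIVFPH"  # no K/R/G: linkers never spawn flank motifs


def neutral_linker(length: int, phase: int = 0) -> str:
    """Deterministic basic-free filler for propeptides, linkers and tails."""
    cyc = itertools.cycle(_LINKER_ALPHABET)
    for _ in range(phase % len(_LINKER_ALPHABET)):
        next(cyc)
    return "".join(next(cyc) for _ in range(length))


def assemble_precursor(
    rule: FamilyRule,
    core: str,
    *,
    signal: str = SYNTHETIC_SIGNAL,
    propeptide_length: int = 22,
    tail_length: int = 12,
    ends_precursor: bool = False,
) -> tuple[str, str]:
    """Assemble a synthetic precursor around a mature core.

    Returns ``(residues, labels)`` where ``labels`` marks each position:
    ``s`` signal, ``p`` propeptide/linker, ``n``/``f`` N-/C-flank motif,
    ``c`` core, ``g`` amide-donor Gly, ``t`` tail.
    """
    parts: list[tuple[str, str]] = [(signal, "s")]
    if rule.location != "post_signal":
        parts.append((neutral_linker(propeptide_length), "p"))
        parts.append((rule.n_flank[0], "n"))
    parts.append((core, "c"))
    if rule.amidated:
        parts.append(("G", "g"))
    if ends_precursor:
        if not rule.c_allows_precursor_end:
            raise ValueError(f"{rule.family_id}: rule does not allow precursor_end")
    else:
        parts.append((rule.c_flank[0], "f"))
        parts.append((neutral_linker(tail_length, phase=5), "t"))
    residues = "".join(s for s, _ in parts)
    labels = "".join(lab * len(s) for s, lab in parts)
    return residues, labels


def build_reference_precursor(
    family_id: str, registry: Sequence[FamilyRule] | None = None
) -> tuple[Precursor, str]:
    """Fixture precursor built around the family's printed reference peptide.

    Returns the precursor and the expected mature core.
    """
    rule = rule_for(family_id, registry)
    ref = REFERENCE_PEPTIDES[rule.family_id]
    residues, _ = assemble_precursor(
        rule, ref.sequence, ends_precursor=ref.ends_precursor
    )
    prec = Precursor(
        id=f"{rule.family_id}_reference",
        residues=residues,
        signal_end=len(SYNTHETIC_SIGNAL),
        family_id=rule.family_id,
        species="synthetic",
        order="reference",
        complete=ref.complete,
    )
    return prec, ref.sequence


# ---------------------------------------------------------------------------
# FASTA / TSV interfaces.  Header dialect:
#   >id|species|order|family|signal_end|complete
# ---------------------------------------------------------------------------


def _header(p: Precursor) -> str:
    return "|".join(
        [p.id, p.species, p.order, p.family_id or "", str(p.signal_end),
         "1" if p.complete else "0"]
    )


def read_precursor_fasta(path) -> list[Precursor]:
    """Parse precursors from FASTA using the pipe-delimited header dialect."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split("|")
        pid = fields[0].strip()
        species = fields[1] if len(fields) > 1 else ""
        order = fields[2] if len(fields) > 2 else ""
        family = fields[3] if len(fields) > 3 and fields[3] else None
        seq = str(rec.seq).upper()
        signal_end = (
            int(fields[4]) if len(fields) > 4 and fields[4] else crude_signal_end(seq)
        )
        complete = fields[5].strip() not in ("0", "false", "False") if len(fields) > 5 else True
        out.append(
            Precursor(pid, seq, signal_end, family, species, order, complete)
        )
    return out


def write_precursor_fasta(precursors: Iterable[Precursor], path) -> None:
    records = [
        SeqRecord(Seq(p.residues), id=_header(p), description="") for p in precursors
    ]
    SeqIO.write(records, str(path), "fasta")


def write_peptide_fasta(
    peptides: Iterable[tuple[Precursor, MaturePeptide]], path
) -> None:
    """Mature cores as FASTA; ids reuse the precursor header dialect."""
    records = [
        SeqRecord(Seq(pep.core), id=_header(prec), description="")
        for prec, pep in peptides
    ]
    SeqIO.write(records, str(path), "fasta")


def peptide_table(peptides: Iterable[tuple[Precursor, MaturePeptide]]):
    """Coordinates, flags and flank motifs as a DataFrame (TSV-ready)."""
    import pandas as pd

    rows = []
    for prec, pep in peptides:
        rows.append(
            {
                "id": prec.id,
                "species": prec.species,
                "order": prec.order,
                "family": pep.family_id,
                "start": pep.start,
                "end": pep.end,
                "length": len(pep.core),
                "core": pep.core,
                "n_motif": pep.n_site.motif if pep.n_site else "",
                "c_motif": pep.c_site.motif if pep.c_site else "",
                "amidated": pep.amidated,
                "pglu": pep.pglu,
                "low_confidence": pep.low_confidence,
                "warnings": ";".join(pep.warnings),
            }
        )
    return pd.DataFrame(rows)
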