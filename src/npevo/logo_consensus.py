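"""Sequence-logo statistics, consensus calling, and ancestral-depth assignment.

A logo column reports the relative frequencies of the 20 residues among
non-gap characters and the information content log2(20) - H in bits, where H
is the Shannon entropy of those frequencies.  No small-sample correction is
applied by default (the closed forms stay exact and testable); the standard
e_n = 19 / (2 ln 2 * n) correction is available as a flag.

Ancestral-depth assignment mirrors presence/absence reasoning over taxon
groups and outgroups: a candidate peptide found (by exact string match,
ignoring PTM flags) across enough polyneopteran orders is called ancestral
for Polyneoptera; a hit in silverfish (Zygentoma) deepens the call to
Pterygota; a hit in Remipedia — or deeper arthropods — to Hexapoda.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

from .alignment_io import MSA
from .family_rules import AA20

#: Maximum per-column information content for a 20-letter alphabet (bits).
MAX_INFO_BITS = math.log2(20)

GAPLIKE = frozenset("-X?")

DEPTH_LADDER = ("undetermined", "Polyneoptera", "Pterygota", "Hexapoda")

#: Default minimum number of taxon groups a candidate must occur in before
#: any ancestral call is made; the ~11 analyzed polyneopteran orders are
#: never all sampled, so this is a configurable interpretation.
DEFAULT_MIN_ORDERS = 5


@dataclass(frozen=True)
class LogoColumn:
    """Per-column residue frequencies (over non-gap characters) and info content."""

    position: int
    freqs: dict[str, float]
    info: float
    gap_fraction: float

    def letter_heights(self) -> dict[str, float]:
        """freq * info per residue; heights sum to the column info."""
        return {aa: f * self.info for aa, f in self.freqs.items()}


@dataclass(frozen=True)
class ConsensusResult:
    """Consensus with lowercase 'x' at positions below threshold (or tied)."""

    sequence: str
    threshold: float
    support: tuple[float, ...]


@dataclass(frozen=True)
class AncestralCall:
    peptide: str
    orders_present: frozenset[str]
    outgroup_hits: frozenset[str]
    depth: str
    min_orders: int
    pre_hexapod: bool = False


def compute_logo(msa: MSA, small_sample_correction: bool = False) -> list[LogoColumn]:
    """Per-column logo statistics; 'X', '?' and '-' count as gaps.

    An all-gap column has info 0 and gap_fraction 1.  With
    ``small_sample_correction`` the info is reduced by e_n = 19/(2 ln2 * n)
    (clipped at 0), n being the column's non-gap count.
    """
    if msa.n_rows < 1:
        raise ValueError("logo requires at least one row")
    columns = []
    for j in range(msa.n_cols):
        col = msa.column(j)
        residues = [c for c in col if c not in GAPLIKE]
        gap_fraction = 1.0 - len(residues) / len(col)
        if not residues:
            columns.append(LogoColumn(j, {}, 0.0, 1.0))
            continue
        counts = Counter(residues)
        n = len(residues)
        freqs = {aa: c / n for aa, c in sorted(counts.items())}
        entropy = -sum(f * math.log2(f) for f in freqs.values())
        info = MAX_INFO_BITS - entropy
        if small_sample_correction:
            info = max(0.0, info - 19.0 / (2.0 * math.log(2) * n))
        columns.append(LogoColumn(j, freqs, info, gap_fraction))
    return columns


def consensus_sequence(msa: MSA, threshold: float = 0.5) -> ConsensusResult:
    """Plurality consensus with ambiguity masking.

    Per column, the plurality non-gap residue is emitted if its fraction of
    the column's non-gap characters reaches ``threshold``; otherwise
    (including ties and all-gap columns) a lowercase 'x' is emitted.
    """
    if msa.n_rows < 1 or msa.n_cols < 1:
        raise ValueError("consensus requires a non-empty alignment")
    if not (0.5 <= threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside [0.5, 1]")
    chars = []
    support = []
    for j in range(msa.n_cols):
        col = [c for c in msa.column(j) if c not in GAPLIKE]
        if not col:
            chars.append("x")
            support.append(0.0)
            continue
        counts = Counter(col).most_common()
        best_aa, best_n = counts[0]
        tied = len(counts) > 1 and counts[1][1] == best_n
        frac = best_n / len(col)
        support.append(frac)
        chars.append("x" if tied or frac < threshold else best_aa)
    return ConsensusResult("".join(chars), threshold, tuple(support))


def _norm_outgroup(name: str) -> str:
    low = name.strip().lower()
    if low == "zygentoma":
        return "Zygentoma"
    if low == "remipedia":
        return "Remipedia"
    return "other"


def assign_ancestral_depth(
    candidate: str,
    occurrence: Mapping[str, bool],
    outgroups: Mapping[str, bool] | None = None,
    min_orders: int = DEFAULT_MIN_ORDERS,
) -> AncestralCall:
    """Assign the clade for which a candidate peptide is plausibly ancestral.

    ``occurrence`` maps taxon group -> presence of the exact candidate
    sequence; ``outgroups`` maps outgroup name -> presence (names other than
    Zygentoma/Remipedia count as deeper, pre-hexapod arthropods).  Depth:
    Hexapoda requires a Remipedia-or-deeper hit, Pterygota a Zygentoma hit,
    Polyneoptera at least ``min_orders`` groups with no outgroup needed;
    below ``min_orders`` the call is undetermined.  Monotone: adding an
    outgroup hit never yields a shallower depth.
    """
    if not candidate:
        raise ValueError("empty candidate peptide")
    present = frozenset(g for g, hit in occurrence.items() if hit)
    hits = frozenset(
        _norm_outgroup(name) for name, hit in (outgroups or {}).items() if hit
    )
    pre_hexapod = "other" in hits
    if len(present) < min_orders:
        depth = "undetermined"
    elif "Remipedia" in hits or pre_hexapod:
        depth = "Hexapoda"
    elif "Zygentoma" in hits:
        depth = "Pterygota"
    else:
        depth = "Polyneoptera"
    return AncestralCall(
        peptide=candidate,
        orders_present=present,
        outgroup_hits=hits,
        depth=depth,
        min_orders=min_orders,
        pre_hexapod=pre_hexapod,
    )


def logo_table(columns: list[LogoColumn]):
    """Per-column letter stacks as a DataFrame (position, residue, height, info)."""
    import pandas as pd

    rows = []
    for col in columns:
        if not col.freqs:
            rows.append(
                {"position": col.position, "residue": "-", "height": 0.0,
                 "info": 0.0, "gap_fraction": col.gap_fraction}
            )
            continue
        for aa, h in col.letter_heights().items():
            rows.append(
                {"position": col.position, "residue": aa, "height": h,
                 "info": col.info, "gap_fraction": col.gap_fraction}
            )
    return pd.DataFrame(rows)
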