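"""Sequence-set and alignment I/O, alignment merging, and gap-aware slicing.

FASTA reading/writing goes through Biopython; '?' and 'X' characters used to
flag unresolved transcript positions are preserved verbatim.  Re-alignment is
never performed in-process: :func:`merge_alignments` either stacks inputs
after terminal-gap padding (a documented approximation) or shells out to an
external aligner through a subprocess hook.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .family_rules import AA20

GAP = "-"
ALIGNMENT_CHARS = frozenset(AA20) | {"X", "?", GAP}


class AlignmentFormatError(ValueError):
    """Ragged alignment or illegal character in a sequence file."""


@dataclass
class SequenceRecord:
    id: str
    residues: str
    metadata: dict = field(default_factory=dict)


@dataclass
class SequenceSet:
    """A list of records, optionally all of equal (aligned) length."""

    records: list[SequenceRecord]
    aligned: bool = False

    def __post_init__(self):
        if self.aligned:
            lengths = {len(r.residues) for r in self.records}
            if len(lengths) > 1:
                detail = ", ".join(
                    f"{r.id}:{len(r.residues)}" for r in self.records
                )
                raise AlignmentFormatError(f"ragged aligned input (row lengths {detail})")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class MSA:
    """A rectangular alignment: row ids plus equal-length residue strings."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise AlignmentFormatError("ids and rows differ in count")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise AlignmentFormatError(f"ragged alignment (row lengths {sorted(widths)})")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    @classmethod
    def from_set(cls, seqset: SequenceSet) -> "MSA":
        return cls([r.id for r in seqset.records], [r.residues for r in seqset.records])


def _parse_metadata(description: str) -> tuple[str, dict]:
    """Parse the pipe-delimited precursor header dialect when present."""
    fields = description.split("|")
    rid = fields[0].strip()
    meta: dict = {}
    keys = ("species", "order", "family", "signal_end", "complete")
    for key, value in zip(keys, fields[1:]):
        if value == "":
            continue
        if key == "signal_end":
            meta[key] = int(value)
        elif key == "complete":
            meta[key] = value.strip() not in ("0", "false", "False")
        else:
            meta[key] = value
    return rid, meta


def read_sequences(path, expect_aligned: bool = False) -> SequenceSet:
    """Read a FASTA file; 'X' and '?' are preserved verbatim.

    Raises :class:`AlignmentFormatError` on illegal characters (naming the
    record and position) or, with ``expect_aligned``, on ragged rows.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rid, meta = _parse_metadata(rec.description)
        residues = str(rec.seq).upper()
        for i, c in enumerate(residues):
            if c not in ALIGNMENT_CHARS:
                raise AlignmentFormatError(
                    f"record {rid!r}: illegal character {c!r} at position {i}"
                )
        records.append(SequenceRecord(rid, residues, meta))
    return SequenceSet(records, aligned=expect_aligned)


def _format_header(rec: SequenceRecord) -> str:
    meta = rec.metadata
    if not meta:
        return rec.id
    complete = meta.get("complete", True)
    return "|".join(
        [
            rec.id,
            str(meta.get("species", "")),
            str(meta.get("order", "")),
            str(meta.get("family", "")),
            str(meta.get("signal_end", "")),
            "1" if complete else "0",
        ]
    )


def write_sequences(seqset: SequenceSet, path) -> None:
    out = [
        SeqRecord(Seq(r.residues), id=_format_header(r), description="")
        for r in seqset.records
    ]
    SeqIO.write(out, str(path), "fasta")


class AlignerHookError(RuntimeError):
    """The external aligner exited nonzero; diagnostics are attached."""


def run_aligner_hook(records: Sequence[SequenceRecord], hook: str) -> list[SequenceRecord]:
    """Run an external aligner over unaligned records.

    ``hook`` is a shell-style command.  If it contains ``{in}``/``{out}``
    placeholders, temporary FASTA paths are substituted; otherwise the
    command reads FASTA on stdin and writes aligned FASTA on stdout
    (e.g. ``"mafft --localpair --maxiterate 1000 -"`` with ``{in}`` as the
    final argument, or plain ``"mafft -"``-style stdin filters).
    """
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fasta"
        fout = Path(tmp) / "out.fasta"
        write_sequences(SequenceSet(list(records)), fin)
        use_files = "{in}" in hook or "{out}" in hook
        cmd = hook.replace("{in}", str(fin)).replace("{out}", str(fout))
        argv = shlex.split(cmd)
        stdin = None if use_files else fin.open("rb")
        try:
            proc = subprocess.run(argv, stdin=stdin, capture_output=True)
        finally:
            if stdin is not None:
                stdin.close()
        if proc.returncode != 0:
            raise AlignerHookError(
                f"aligner hook {hook!r} exited {proc.returncode}: "
                f"{proc.stderr.decode(errors='replace')[:2000]}"
            )
        if "{out}" in hook:
            aligned = read_sequences(fout, expect_aligned=True)
        else:
            fout.write_bytes(proc.stdout)
            aligned = read_sequences(fout, expect_aligned=True)
    by_id = {r.id: r for r in aligned.records}
    # keep input order and metadata
    out = []
    for rec in records:
        arec = by_id.get(rec.id.split("|")[0], by_id.get(rec.id))
        if arec is None:
            raise AlignerHookError(f"aligner hook dropped record {rec.id!r}")
        out.append(SequenceRecord(rec.id, arec.residues, dict(rec.metadata)))
    return out


def merge_alignments(per_group: Sequence[MSA], realign_hook: str | None = None) -> MSA:
    """Merge per-group alignments into one cross-group alignment.

    With ``realign_hook``, rows are de-gapped, concatenated and re-aligned by
    the external command.  Without a hook, inputs are stacked after padding
    to a common width with terminal gaps — an approximation that keeps
    within-group columns intact but does not align across groups.
    """
    if not per_group:
        raise ValueError("merge_alignments requires at least one input MSA")
    if len(per_group) == 1 and realign_hook is None:
        return per_group[0]
    if realign_hook is not None:
        records = [
            SequenceRecord(rid, row.replace(GAP, ""))
            for msa in per_group
            for rid, row in zip(msa.ids, msa.rows)
        ]
        aligned = run_aligner_hook(records, realign_hook)
        return MSA([r.id for r in aligned], [r.residues for r in aligned])
    width = max(msa.n_cols for msa in per_group)
    ids, rows = [], []
    for msa in per_group:
        for rid, row in zip(msa.ids, msa.rows):
            ids.append(rid)
            rows.append(row + GAP * (width - len(row)))
    return MSA(ids, rows)


def ungapped_to_column_map(row: str) -> list[int]:
    """Column index of each ungapped residue of an alignment row."""
    return [j for j, c in enumerate(row) if c != GAP]


def slice_peptide_columns(msa: MSA, peptides: Mapping[str, tuple[int, int]]) -> MSA:
    """Sub-alignment covering the mature cores, mapped through gaps.

    ``peptides`` maps row id to 0-based half-open coordinates in that row's
    ungapped sequence.  A column is kept if any row's core covers it (union
    rule), so indels inside peptides are preserved.
    """
    if not peptides:
        raise ValueError("no peptide coordinates given")
    keep: set[int] = set()
    for rid, row in zip(msa.ids, msa.rows):
        coords = peptides.get(rid)
        if coords is None:
            continue
        start, end = coords
        cmap = ungapped_to_column_map(row)
        if end > len(cmap) or start < 0 or start > end:
            raise ValueError(
                f"row {rid!r}: core coordinates ({start}, {end}) exceed "
                f"ungapped length {len(cmap)}"
            )
        keep.update(cmap[start:end])
    if not keep:
        raise ValueError("no rows matched the given peptide coordinates")
    cols = sorted(keep)
    return MSA(list(msa.ids), ["".join(row[j] for j in cols) for row in msa.rows])
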