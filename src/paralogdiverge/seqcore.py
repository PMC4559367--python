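"""Domain types and I/O for coding-sequence datasets.

A dataset is a set of coding sequences (CDS) carrying per-sequence
metadata: species, paralog group (two copies of a duplicated gene, e.g.
erk1/erk2) and a clade label.  Downstream rate analysis operates on
*codon alignments*: nucleotide alignments whose gaps respect the reading
frame, normally obtained by aligning the proteins and back-translating
each residue to its source codon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

GAP = "-"
PARALOG_LABELS = ("P1", "P2", "unassigned")

#: map common paralog spellings onto the canonical labels
_PARALOG_ALIASES = {
    "p1": "P1", "erk1": "P1", "mapk3": "P1", "1": "P1",
    "p2": "P2", "erk2": "P2", "mapk1": "P2", "2": "P2",
}


class SequenceError(ValueError):
    """Raised for malformed or inconsistent sequence input."""


@dataclass(frozen=True)
class SequenceRecord:
    """A coding sequence with its grouping metadata.

    ``nucleotides`` is an uppercase string over ``ACGT-N``; for a CDS the
    ungapped length must be a multiple of three with no internal stop.
    """

    id: str
    nucleotides: str
    species: str = ""
    paralog: str = "unassigned"
    clade: str = ""
    is_cds: bool = True

    def __post_init__(self):
        if self.paralog not in PARALOG_LABELS:
            raise SequenceError(
                f"{self.id}: paralog must be one of {PARALOG_LABELS}, got {self.paralog!r}"
            )

    @property
    def ungapped(self) -> str:
        return self.nucleotides.replace(GAP, "")


@dataclass(frozen=True)
class ProteinAlignment:
    """Aligned amino-acid rows (gap ``-``), all of equal length."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self):
        lengths = {len(s) for _, s in self.records}
        if len(lengths) > 1:
            raise SequenceError(f"ragged protein alignment: row lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.records)

    def row(self, rid: str) -> str:
        for i, s in self.records:
            if i == rid:
                return s
        raise KeyError(rid)


@dataclass(frozen=True)
class CodonAlignment:
    """Frame-respecting nucleotide alignment.

    Every row has length ``3 * n_codons`` and every gap run is a whole
    number of codons, so column *c* (1-based) of every row is a codon or
    ``---``.  ``meta`` maps row ids to their :class:`SequenceRecord`.
    """

    records: tuple[tuple[str, str], ...]
    meta: Mapping[str, SequenceRecord] = field(default_factory=dict)
    source_columns: tuple[int, ...] | None = None  # 1-based columns of the parent alignment

    def __post_init__(self):
        lengths = {len(s) for _, s in self.records}
        if len(lengths) > 1:
            raise SequenceError(f"ragged codon alignment: row lengths {sorted(lengths)}")
        if lengths and next(iter(lengths)) % 3:
            raise SequenceError("codon alignment row length not a multiple of 3")

    @property
    def n_codons(self) -> int:
        return len(self.records[0][1]) // 3 if self.records else 0

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.records)

    def row(self, rid: str) -> str:
        for i, s in self.records:
            if i == rid:
                return s
        raise KeyError(rid)

    def codons(self, rid: str) -> list[str]:
        s = self.row(rid)
        return [s[i : i + 3] for i in range(0, len(s), 3)]

    def subset(self, ids: Iterable[str]) -> "CodonAlignment":
        wanted = list(ids)
        missing = set(wanted) - set(self.ids)
        if missing:
            raise KeyError(f"ids not in alignment: {sorted(missing)}")
        return CodonAlignment(
            records=tuple((i, s) for i, s in self.records if i in set(wanted)),
            meta={k: v for k, v in self.meta.items() if k in set(wanted)},
            source_columns=self.source_columns,
        )

    def ids_by(self, paralog: str | None = None, clade: str | None = None) -> list[str]:
        out = []
        for i in self.ids:
            m = self.meta.get(i)
            if m is None:
                continue
            if paralog is not None and m.paralog != paralog:
                continue
            if clade is not None and m.clade != clade:
                continue
            out.append(i)
        return out


@dataclass(frozen=True)
class GeneSizeTable:
    """Gene sizes (ATG to stop, kilobases) per species and paralog group."""

    rows: tuple[tuple[str, str, float], ...]  # (species, paralog, size_kb)

    def __post_init__(self):
        for sp, par, kb in self.rows:
            if kb <= 0:
                raise SequenceError(f"gene size must be positive: {sp}/{par} = {kb}")

    def sizes(self, paralog: str) -> list[float]:
        return [kb for _, par, kb in self.rows if par == paralog]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["species", "paralog", "size_kb"])


# ---------------------------------------------------------------------------
# genetic code helpers

def _code_table(code: int = 1) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[code]


def stop_codons(code: int = 1) -> frozenset[str]:
    return frozenset(_code_table(code).stop_codons)


def sense_codons(code: int = 1) -> tuple[str, ...]:
    return tuple(sorted(_code_table(code).forward_table))


def translate_codon(codon: str, code: int = 1) -> str:
    """One codon to one residue: stops map to ``*``, codons with N to ``X``."""
    table = _code_table(code)
    if "N" in codon:
        return "X"
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


def translate(cds: str, code: int = 1) -> str:
    """Translate an ungapped CDS; terminal stop dropped, internal stop is an error."""
    if len(cds) % 3:
        raise SequenceError(f"CDS length {len(cds)} not a multiple of 3")
    if GAP in cds:
        raise SequenceError("translate expects an ungapped CDS")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in stop_codons(code):
        codons = codons[:-1]
    residues = []
    for k, codon in enumerate(codons, start=1):
        aa = translate_codon(codon, code)
        if aa == "*":
            raise SequenceError(f"internal stop codon {codon} at codon {k}")
        residues.append(aa)
    return "".join(residues)


# ---------------------------------------------------------------------------
# I/O

def normalize_nucleotides(seq: str) -> str:
    return seq.upper().replace("U", "T").replace(".", GAP)


def read_metadata(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a tab-separated metadata table with columns id, species, paralog, clade."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"id", "species", "paralog", "clade"}
    if not required.issubset(df.columns):
        raise SequenceError(f"metadata must have columns {sorted(required)}")
    out = {}
    for _, r in df.iterrows():
        out[r["id"]] = {
            "species": r["species"],
            "paralog": _PARALOG_ALIASES.get(r["paralog"].strip().lower(), "unassigned"),
            "clade": r["clade"],
        }
    return out


def read_fasta(
    path: str | Path,
    metadata: Mapping[str, Mapping[str, str]] | None = None,
    code: int = 1,
    is_cds: bool = True,
) -> list[SequenceRecord]:
    """Read sequences, attach metadata, and validate CDS framing.

    Sequences are uppercased with U mapped to T and ``.`` to ``-``.  CDS
    entries whose ungapped length is not a multiple of three, or that
    contain an internal stop, are excluded with a logged warning rather
    than trimmed (trimming could silently shift the reading frame).
    Duplicate ids are an error.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise SequenceError(f"duplicate sequence id {entry.id!r}")
        seen.add(entry.id)
        seq = normalize_nucleotides(str(entry.seq))
        meta = dict(metadata.get(entry.id, {})) if metadata else {}
        rec = SequenceRecord(
            id=entry.id,
            nucleotides=seq,
            species=meta.get("species", ""),
            paralog=meta.get("paralog", "unassigned"),
            clade=meta.get("clade", ""),
            is_cds=is_cds,
        )
        if is_cds:
            ungapped = rec.ungapped
            if len(ungapped) % 3:
                logger.warning(
                    "excluding %s: CDS length %d not a multiple of 3", rec.id, len(ungapped)
                )
                continue
            try:
                translate(ungapped, code)
            except SequenceError as exc:
                logger.warning("excluding %s: %s", rec.id, exc)
                continue
        records.append(rec)
    return records


def write_fasta(records: Iterable[tuple[str, str]] | CodonAlignment, path: str | Path) -> None:
    if isinstance(records, CodonAlignment):
        records = records.records
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_metadata(records: Iterable[SequenceRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.id, r.species, r.paralog, r.clade) for r in records],
        columns=["id", "species", "paralog", "clade"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_sizes(path: str | Path) -> GeneSizeTable:
    """Tab-separated gene-size table with columns species, paralog, size_kb."""
    df = pd.read_csv(path, sep="\t")
    rows = tuple(
        (str(r["species"]), _PARALOG_ALIASES.get(str(r["paralog"]).strip().lower(), str(r["paralog"])), float(r["size_kb"]))
        for _, r in df.iterrows()
    )
    return GeneSizeTable(rows=rows)


# ---------------------------------------------------------------------------
# alignment construction

def protein_alignment_from_records(
    records: Sequence[SequenceRecord], code: int = 1
) -> ProteinAlignment:
    """Trivial protein 'alignment' of already length-matched translations."""
    rows = tuple((r.id, translate(r.ungapped, code)) for r in records)
    return ProteinAlignment(records=rows)


def backtranslate_alignment(
    prot: ProteinAlignment,
    cds_records: Sequence[SequenceRecord],
    code: int = 1,
) -> CodonAlignment:
    """Expand each aligned residue to its source codon (gap -> ``---``).

    Each protein row, gaps stripped, must equal the translation of the
    matching CDS; any mismatch is an error naming the row and column.
    A terminal stop codon on the CDS is dropped, mirroring translation.
    """
    by_id = {r.id: r for r in cds_records}
    out_rows = []
    for rid, prow in prot.records:
        if rid not in by_id:
            raise SequenceError(f"no CDS provided for aligned protein {rid!r}")
        cds = by_id[rid].ungapped
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons and codons[-1] in stop_codons(code):
            codons = codons[:-1]
        nt_row = []
        k = 0
        for col, aa in enumerate(prow, start=1):
            if aa == GAP:
                nt_row.append("---")
                continue
            if k >= len(codons):
                raise SequenceError(f"{rid}: protein row longer than CDS at column {col}")
            codon = codons[k]
            if translate_codon(codon, code) != aa:
                raise SequenceError(
                    f"{rid}: residue {aa!r} at column {col} does not match codon {codon!r}"
                )
            nt_row.append(codon)
            k += 1
        if k != len(codons):
            raise SequenceError(f"{rid}: CDS has {len(codons) - k} codons beyond the protein row")
        out_rows.append((rid, "".join(nt_row)))
    meta = {r.id: r for r in cds_records if r.id in prot.ids}
    return CodonAlignment(records=tuple(out_rows), meta=meta)


def complete_codon_columns(
    aln: CodonAlignment, scope: Iterable[str] | None = None
) -> CodonAlignment:
    """Keep only codon columns with no gap and no N in any in-scope row.

    This is the complete-deletion convention used for whole-alignment rate
    summaries; the retained original column indices (1-based) are recorded
    on the result as ``source_columns``.  Idempotent.
    """
    scope_ids = list(scope) if scope is not None else list(aln.ids)
    if not scope_ids:
        raise SequenceError("complete_codon_columns: empty scope")
    rows = {rid: aln.codons(rid) for rid in aln.ids}
    keep: list[int] = []
    for c in range(aln.n_codons):
        ok = all(GAP not in rows[rid][c] and "N" not in rows[rid][c] for rid in scope_ids)
        if ok:
            keep.append(c)
    parent_cols = aln.source_columns or tuple(range(1, aln.n_codons + 1))
    new_rows = tuple(
        (rid, "".join(rows[rid][c] for c in keep)) for rid, _ in aln.records
    )
    return CodonAlignment(
        records=new_rows,
        meta=dict(aln.meta),
        source_columns=tuple(parent_cols[c] for c in keep),
    )


def protein_rows(aln: CodonAlignment, code: int = 1) -> ProteinAlignment:
    """Column-wise translation of a codon alignment (gap codon -> gap residue)."""
    rows = []
    for rid, s in aln.records:
        residues = []
        for i in range(0, len(s), 3):
            codon = s[i : i + 3]
            residues.append(GAP if codon == "---" else translate_codon(codon, code))
        rows.append((rid, "".join(residues)))
    return ProteinAlignment(records=tuple(rows))
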