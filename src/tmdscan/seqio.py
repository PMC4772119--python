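"""Reading and writing protein sequences and their annotations.

Sequences come in as FASTA; per-record metadata (group label and membrane
topology, i.e. which terminus faces the cytosol) comes in as a TSV with
columns ``id``, ``group``, ``topology``. Topology is a user-supplied
annotation, not a prediction.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids; X is additionally accepted and scored 0.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")


class Topology(enum.Enum):
    """Which terminus of the protein is cytosolic."""

    N_CYTO = "N_CYTO"
    C_CYTO = "C_CYTO"
    UNKNOWN = "UNKNOWN"


@dataclasses.dataclass
class ProteinRecord:
    """A single protein sequence with its group and topology annotation."""

    id: str
    sequence: str
    group: str = ""
    topology: Topology = Topology.UNKNOWN

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        bad = sorted(set(self.sequence) - ALPHABET)
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-standard residues {''.join(bad)!r}; "
                f"allowed: 20 standard amino acids and X"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class FastaParseError(ValueError):
    pass


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased and whitespace-stripped; record order is
    preserved. The file must start with a ``>`` header, contain at least
    one entry and use only the 20 standard residues plus X.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FastaParseError(
                f"{path}:{lineno}: expected FASTA header '>' before sequence data"
            )
        break
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = "".join(str(entry.seq).split()).upper()
        if entry.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {entry.id!r}")
        seen.add(entry.id)
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found (empty dataset)")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


def read_annotations(path: str | Path) -> dict[str, tuple[str, Topology]]:
    """Read the annotation TSV, mapping id -> (group, topology)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["id", "group", "topology"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    dupes = df["id"][df["id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate id(s): {sorted(set(dupes))}")
    annotations: dict[str, tuple[str, Topology]] = {}
    allowed = ", ".join(t.value for t in Topology)
    for row in df.itertuples(index=False):
        try:
            topo = Topology(row.topology)
        except ValueError:
            raise ValueError(
                f"{path}: unknown topology {row.topology!r} for id {row.id!r}; "
                f"allowed values: {allowed}"
            ) from None
        annotations[row.id] = (row.group if pd.notna(row.group) else "", topo)
    return annotations


def write_annotations(
    records: Iterable[ProteinRecord], path: str | Path
) -> None:
    rows = [
        {"id": r.id, "group": r.group, "topology": r.topology.value}
        for r in records
    ]
    pd.DataFrame(rows, columns=["id", "group", "topology"]).to_csv(
        path, sep="\t", index=False
    )


def attach_annotations(
    records: Iterable[ProteinRecord],
    annotations: dict[str, tuple[str, Topology]],
    strict: bool = True,
) -> list[ProteinRecord]:
    """Bind group/topology annotations onto sequence records.

    In strict mode every record id must be annotated; in lenient mode
    unannotated records get an empty group and UNKNOWN topology.
    """
    out: list[ProteinRecord] = []
    for rec in records:
        if rec.id in annotations:
            group, topo = annotations[rec.id]
            out.append(ProteinRecord(rec.id, rec.sequence, group, topo))
        elif strict:
            raise KeyError(f"record {rec.id!r} has no annotation row")
        else:
            out.append(ProteinRecord(rec.id, rec.sequence, "", Topology.UNKNOWN))
    return out
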