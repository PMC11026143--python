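"""Alignment container plus FASTA / relaxed-PHYLIP readers and writers."""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from pathlib import Path

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment

__all__ = ["Alignment", "read_alignment", "write_fasta", "write_phylip"]


@dataclass(frozen=True)
class Alignment:
    """A gap-free multiple alignment: parallel tuples of names and sequences."""

    names: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences):
            raise ValueError("names and sequences differ in count")
        if len(self.names) == 0:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")

    @property
    def n_taxa(self) -> int:
        return len(self.names)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def _to_biopython(self) -> MultipleSeqAlignment:
        return MultipleSeqAlignment(
            SeqRecord(Seq(s), id=name, description="")
            for name, s in zip(self.names, self.sequences)
        )


def _from_records(records) -> Alignment:
    names = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)
    return Alignment(names=names, sequences=seqs)


def read_alignment(path: str | Path, fmt: str | None = None) -> Alignment:
    """Read an alignment from FASTA or relaxed PHYLIP (format sniffed by suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "phylip-relaxed" if path.suffix.lower() in {".phy", ".phylip"} else "fasta"
    if fmt == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences found in {path}")
        return _from_records(records)
    return _from_records(AlignIO.read(str(path), fmt))


def write_fasta(alignment: Alignment, path: str | Path) -> None:
    SeqIO.write(alignment._to_biopython(), str(path), "fasta")


def write_phylip(alignment: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        AlignIO.write(alignment._to_biopython(), fh, "phylip-relaxed")


def alignment_to_fasta_str(alignment: Alignment) -> str:
    buf = StringIO()
    SeqIO.write(alignment._to_biopython(), buf, "fasta")
    return buf.getvalue()
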