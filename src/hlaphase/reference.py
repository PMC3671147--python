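"""Amplicon references and gene models.

An amplicon reference is the single alignment target for one HLA gene:
the full genomic segment amplified by long-range PCR, annotated with the
primer landing sites at either end and the exon intervals of the gene.
All intervals are 0-based, half-open; conversion to 1-based coordinates
happens only at SAM/VCF emission.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["AmpliconReference", "read_reference_fasta", "write_reference_fasta",
           "write_gene_model_bed", "read_gene_model_bed"]


@dataclass
class AmpliconReference:
    """One gene's amplicon sequence plus its gene model.

    Parameters
    ----------
    name : str
        Gene name (e.g. ``"HLA-B"``); used as the SAM/VCF contig name.
    sequence : str
        Uppercase nucleotide sequence of the full amplicon.
    primer_intervals : list of (int, int)
        Primer landing sites at the amplicon ends, 0-based half-open.
    exons : list of (int, int)
        Exon intervals in genomic order, 0-based half-open, non-overlapping.
    coding_frame : int or None
        Reading-frame offset of the first exon base (0 if the concatenated
        exons start at a codon boundary). ``None`` disables synonymy calls.
    """

    name: str
    sequence: str
    primer_intervals: list[tuple[int, int]] = field(default_factory=list)
    exons: list[tuple[int, int]] = field(default_factory=list)
    coding_frame: int | None = 0

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.exons = sorted(tuple(e) for e in self.exons)
        for (a, b) in self.exons:
            if not (0 <= a < b <= len(self)):
                raise ValueError(f"exon interval ({a},{b}) outside reference {self.name}")

    def __len__(self) -> int:
        return len(self.sequence)

    def is_exonic(self, position: int) -> bool:
        return any(a <= position < b for a, b in self.exons)

    @property
    def trimmed_interval(self) -> tuple[int, int]:
        """Interval between the primer intervals (primers excluded)."""
        if not self.primer_intervals:
            return (0, len(self))
        start = max(b for a, b in self.primer_intervals if a == 0) if any(
            a == 0 for a, b in self.primer_intervals) else 0
        end = min(a for a, b in self.primer_intervals if b == len(self)) if any(
            b == len(self) for a, b in self.primer_intervals) else len(self)
        return (start, end)


def write_reference_fasta(references: list[AmpliconReference], path: str) -> None:
    with open(path, "w") as fh:
        for ref in references:
            fh.write(f">{ref.name}\n")
            for i in range(0, len(ref.sequence), 80):
                fh.write(ref.sequence[i:i + 80] + "\n")


def read_reference_fasta(path: str) -> dict[str, str]:
    """Plain FASTA reader returning name → sequence (first header token)."""
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_gene_model_bed(ref: AmpliconReference, path: str) -> None:
    """BED-like TSV: chrom, start, end, feature (0-based half-open)."""
    with open(path, "w") as fh:
        for a, b in ref.primer_intervals:
            fh.write(f"{ref.name}\t{a}\t{b}\tprimer\n")
        for i, (a, b) in enumerate(ref.exons, 1):
            fh.write(f"{ref.name}\t{a}\t{b}\texon{i}\n")


def read_gene_model_bed(path: str, sequences: dict[str, str]) -> dict[str, AmpliconReference]:
    refs: dict[str, AmpliconReference] = {}
    primers: dict[str, list] = {}
    exons: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, a, b, feat = line.rstrip("\n").split("\t")[:4]
            target = primers if feat == "primer" else exons
            target.setdefault(chrom, []).append((int(a), int(b)))
    for name, seq in sequences.items():
        refs[name] = AmpliconReference(
            name=name, sequence=seq,
            primer_intervals=primers.get(name, []),
            exons=sorted(exons.get(name, [])),
        )
    return refs
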