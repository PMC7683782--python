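"""Transcript models and genome sequence access.

All intervals are 0-based half-open on the genomic forward strand.
Transcript-orientation sequence for minus-strand models is obtained by
reverse-complementing the concatenated forward-strand slices.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Mapping, Sequence

from Bio.Seq import Seq

Interval = tuple[int, int]


def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Return the uppercase forward-strand sequence of ``chrom[start:end]``.

    ``genome`` may be a plain mapping of contig name to string or a
    ``pyfaidx.Fasta``-like object supporting ``genome[chrom][start:end]``.
    Out-of-range requests are clamped to the contig.
    """
    seq = genome[chrom]
    start = max(0, start)
    piece = seq[start:end]
    return str(piece).upper()


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_to_stop(nt: str) -> str:
    """Translate codon-by-codon, stopping at (and excluding) the first stop.

    A trailing partial codon is ignored.
    """
    prot = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        aa = str(Seq(nt[i : i + 3]).translate())
        if aa == "*":
            break
        prot.append(aa)
    return "".join(prot)


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one annotated isoform.

    ``exons`` and ``cds`` are genomic 0-based half-open intervals sorted by
    genomic start; strand handling is done by the accessor methods, which
    always work in transcript (5'->3') orientation.
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    biotype: str
    chrom: str
    strand: str
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(iv) for iv in self.exons)
        self.cds = sorted(tuple(iv) for iv in self.cds)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def cds_phase_ok(self) -> bool:
        return self.is_coding and self.cds_length % 3 == 0

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    # -- position bookkeeping -------------------------------------------------

    def _positions(self, intervals: Sequence[Interval]) -> list[int]:
        """Genomic position of every base, in transcript orientation."""
        pos: list[int] = []
        if self.strand == "+":
            for s, e in intervals:
                pos.extend(range(s, e))
        else:
            for s, e in reversed(intervals):
                pos.extend(range(e - 1, s - 1, -1))
        return pos

    @cached_property
    def cds_positions(self) -> list[int]:
        return self._positions(self.cds)

    @cached_property
    def exon_positions(self) -> list[int]:
        return self._positions(self.exons)

    @cached_property
    def _cds_index(self) -> dict[int, int]:
        return {g: i for i, g in enumerate(self.cds_positions)}

    @cached_property
    def _exon_index(self) -> dict[int, int]:
        return {g: i for i, g in enumerate(self.exon_positions)}

    def genomic_to_cds(self, gpos: int) -> int | None:
        """0-based offset into the spliced CDS, or None outside the CDS."""
        return self._cds_index.get(gpos)

    def genomic_to_exonic(self, gpos: int) -> int | None:
        return self._exon_index.get(gpos)

    def contains_exonic(self, gpos: int) -> bool:
        return any(s <= gpos < e for s, e in self.exons)

    def contains_intronic(self, gpos: int) -> bool:
        s, e = self.span
        return s <= gpos < e and not self.contains_exonic(gpos)

    # -- sequence accessors ---------------------------------------------------

    def spliced_cds(self, genome) -> str:
        seq = "".join(fetch(genome, self.chrom, s, e) for s, e in self.cds)
        return revcomp(seq) if self.strand == "-" else seq

    def spliced_exonic(self, genome) -> str:
        seq = "".join(fetch(genome, self.chrom, s, e) for s, e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq

    def base_at(self, genome, gpos: int) -> str:
        """Transcript-strand base at a genomic position."""
        b = fetch(genome, self.chrom, gpos, gpos + 1)
        return revcomp(b) if self.strand == "-" else b

    def downstream_of_cds(self, genome, length: int) -> str:
        """Transcript-orientation sequence following the last CDS base.

        Remaining exonic (3' UTR) sequence first, then plain genomic
        sequence past the transcript end, up to ``length`` bases or the
        contig boundary.
        """
        if not self.cds:
            return ""
        last = self.cds_positions[-1]
        ex = self.exon_positions
        idx = self._exon_index.get(last)
        out = ""
        if idx is not None:
            tail_pos = ex[idx + 1 :]
            if tail_pos:
                # exonic tail is contiguous runs on the genome; fetch per run
                out = self._fetch_positions(genome, tail_pos)
        if len(out) < length:
            need = length - len(out)
            if self.strand == "+":
                gstart = self.exons[-1][1]
                out += fetch(genome, self.chrom, gstart, gstart + need)
            else:
                gend = self.exons[0][0]
                out += revcomp(fetch(genome, self.chrom, gend - need, gend))
        return out[:length]

    def exonic_from(self, genome, gpos: int, length: int) -> str:
        """Transcript-orientation exonic sequence starting at ``gpos``."""
        idx = self._exon_index.get(gpos)
        if idx is None:
            return ""
        return self._fetch_positions(genome, self.exon_positions[idx : idx + length])

    def _fetch_positions(self, genome, positions: list[int]) -> str:
        if not positions:
            return ""
        runs: list[tuple[int, int]] = []
        step = 1 if self.strand == "+" else -1
        run_start = prev = positions[0]
        for p in positions[1:]:
            if p != prev + step:
                runs.append((run_start, prev))
                run_start = p
            prev = p
        runs.append((run_start, prev))
        out = []
        for a, b in runs:
            if self.strand == "+":
                out.append(fetch(genome, self.chrom, a, b + 1))
            else:
                out.append(revcomp(fetch(genome, self.chrom, b, a + 1)))
        return "".join(out)


def open_genome(path) -> Mapping[str, str]:
    """Open a FASTA for random access (pyfaidx, raw-string mode)."""
    from pyfaidx import Fasta

    return Fasta(str(path), as_raw=True, sequence_always_upper=True)
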