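"""Seeded synthetic fixture generator with planted ground truth.

Emulates, at toy scale, every input the pipeline consumes: a multi-contig
genome (including a mitochondrial contig, an immunoglobulin locus and a
lincRNA), a GENCODE-dialect GTF, per-caller somatic VCFs, an indel VCF,
fusion BEDPE calls covering every filter class, isoform expression,
three-source HLA call lists and phasing RNA reads in SAM. Every planted
event is recorded in a truth table that :func:`truth_check` compares
against pipeline output.

The same seed always produces byte-identical files; planted peptide
contexts use a fixed preferred-codon table so the nucleotide encodings
are stable.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .errors import GenerationError
from .transcript import TranscriptModel, revcomp, translate_to_stop

# one codon per amino acid; chosen once so planted contexts are byte-stable
PREF_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "AGC", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
    "*": "TAA",
}
_AA_OF = {v: k for k, v in PREF_CODON.items()}
_FILL = "ARNDCQEGHILKMFPSTWYV"

from .consensus import INDEL_SOURCE

CALLERS = ("muse", "mutect", "radia", "sniper", "strelka")

#: worked-example contexts planted into the fixture
SNV_CONTEXT = "RFVQGKDWGFKKFIRRDFL"   # residues 124-142 of GENEA; F at 133
FUSION_FLANK5 = "DNSKMALNS"
FUSION_FLANK3 = "EALSVVSED"
FUSION_STOP_NT = "GAACTGAGCTAA"       # E L S stop after the junction

#: mock-predictor anchor motifs guaranteeing binders among planted peptides
DEFAULT_MOTIFS = ("KDWG", "MALNS")


def codons(protein: str) -> str:
    return "".join(PREF_CODON[aa] for aa in protein)


def compose_protein(length: int, planted: dict[int, str] | None = None) -> str:
    """Cyclic-filler protein of ``length`` residues with planted substrings.

    ``planted`` maps 1-based start residues to amino-acid strings; residue
    1 is always M.
    """
    seq = list(("M" + _FILL * (length // len(_FILL) + 2))[:length])
    for start, aas in (planted or {}).items():
        if start + len(aas) - 1 > length:
            raise GenerationError(f"planted context at {start} exceeds protein length")
        seq[start - 1 : start - 1 + len(aas)] = list(aas)
    return "".join(seq)


def snv_encoding(codon: str, to_aa: str) -> tuple[int, str]:
    """Find a single-base change turning ``codon`` into an ``to_aa`` codon."""
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1 :]
            if translate_to_stop(mut + "TAA")[:1] == to_aa:
                return i, b
    raise GenerationError(f"no single-base change from {codon} to {to_aa}")


# ---------------------------------------------------------------------------
# gene construction
# ---------------------------------------------------------------------------

@dataclass
class BuiltGene:
    name: str
    biotype: str
    chrom: str
    strand: str
    g_start: int
    local_seq: str                    # transcript-forward, intron included
    exons_local: list[tuple[int, int]]
    cds_local: list[tuple[int, int]]
    protein: str = ""
    model: TranscriptModel | None = None

    @property
    def g_end(self) -> int:
        return self.g_start + len(self.local_seq)

    def genomic_chunk(self) -> str:
        return revcomp(self.local_seq) if self.strand == "-" else self.local_seq

    def _map(self, iv: tuple[int, int]) -> tuple[int, int]:
        s, e = iv
        if self.strand == "-":
            length = len(self.local_seq)
            return (self.g_start + length - e, self.g_start + length - s)
        return (self.g_start + s, self.g_start + e)

    def finish(self) -> None:
        self.model = TranscriptModel(
            transcript_id=f"{self.name}.t1", gene_id=self.name, gene_name=self.name,
            biotype=self.biotype, chrom=self.chrom, strand=self.strand,
            exons=[self._map(iv) for iv in self.exons_local],
            cds=[self._map(iv) for iv in self.cds_local],
        )


def build_gene(
    name: str, chrom: str, strand: str, g_start: int, rng: random.Random,
    protein: str = "", biotype: str = "protein_coding",
    utr5: int = 40, utr3: int = 40,
    intron_after: int | None = None, intron_len: int = 100,
    cds_nt: str | None = None, exon_len: int | None = None,
) -> BuiltGene:
    """Lay out one gene locally and map it onto the genome.

    ``intron_after`` is a spliced-transcript offset at which a single
    intron is inserted. ``cds_nt`` overrides the preferred-codon encoding
    of ``protein`` (the stop codon is appended automatically either way).
    Non-coding genes pass ``protein=""`` and ``exon_len``.
    """
    if protein:
        body = cds_nt if cds_nt is not None else codons(protein)
        body += PREF_CODON["*"]
        tx = _dna(rng, utr5) + body + _dna(rng, utr3)
        cds_spliced = (utr5, utr5 + len(body))
    else:
        tx = _dna(rng, exon_len or 200)
        cds_spliced = None
    if intron_after is not None:
        intron = "GT" + _dna(rng, intron_len - 4) + "AG"
        local = tx[:intron_after] + intron + tx[intron_after:]
        exons = [(0, intron_after), (intron_after + intron_len, len(local))]
    else:
        local = tx
        exons = [(0, len(local))]
    cds_local: list[tuple[int, int]] = []
    if cds_spliced:
        spliced_cursor = 0
        for s, e in exons:
            a = max(cds_spliced[0], spliced_cursor)
            b = min(cds_spliced[1], spliced_cursor + (e - s))
            if a < b:
                cds_local.append((s + (a - spliced_cursor), s + (b - spliced_cursor)))
            spliced_cursor += e - s
    gene = BuiltGene(name, biotype, chrom, strand, g_start, local,
                     exons, cds_local, protein=protein)
    gene.finish()
    return gene


def _dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choices("ACGT", k=n))


# ---------------------------------------------------------------------------
# fixture spec and generation
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    """Parameters of the default synthetic study.

    The planted variant/fusion/expression plan itself is fixed — it *is*
    the study design — only the seed and contig sizes are tunable.
    """

    seed: int = 17
    chr1_len: int = 6000
    chr2_len: int = 604_000
    chrf_len: int = 2000
    chrm_len: int = 2000
    read_len: int = 45
    fusion_support: int = 37
    tpm: dict[str, float] = field(default_factory=lambda: {
        "GENEA": 120.5, "GENEB": 8.2, "GENEC": 33.0, "GENED": 15.0,
        "GENEE": 0.0, "LINC1": 4.0, "IG1": 2.0, "IG2": 2.0,
        "FUS5": 50.0, "FUS3": 30.0, "FUS3S": 10.0,
        "RT1": 5.0, "RT2": 5.0, "RT3": 5.0, "RT4": 5.0,
        "MT1": 100.0, "MT2": 100.0,
    })


def _window(wt: str, mut: str, indices: list[int], n: int, frameshift: bool) -> tuple[str, str | None]:
    """Planted-truth peptide window (mirror of the flank rule)."""
    start = max(0, min(indices) - (n - 1))
    end = min(len(mut), max(indices) + n)
    return mut[start:end], (None if frameshift else wt[start:end])


@dataclass
class TruthRow:
    category: str
    key: str
    expected: str


class FixtureSet:
    """Handles to the generated files and in-memory plan."""

    def __init__(self, outdir: Path):
        self.outdir = Path(outdir).resolve()
        self.paths: dict[str, Path] = {}
        self.genes: dict[str, BuiltGene] = {}
        self.truth: list[TruthRow] = []

    def path(self, key: str) -> Path:
        return self.paths[key]


def make_fixture(spec: FixtureSpec | None = None, outdir=".") -> FixtureSet:
    """Generate the complete toy input set plus truth table under ``outdir``."""
    spec = spec or FixtureSpec()
    rng = random.Random(spec.seed)
    out = FixtureSet(Path(outdir))
    out.outdir.mkdir(parents=True, exist_ok=True)

    contig_lens = {
        "chr1": spec.chr1_len, "chr2": spec.chr2_len,
        "chrF3": spec.chrf_len, "chrF5": spec.chrf_len, "chrM": spec.chrm_len,
    }
    contigs = {name: list(_dna(rng, n)) for name, n in sorted(contig_lens.items())}

    # -- proteins with planted contexts --------------------------------------
    prot_a = compose_protein(160, {124: SNV_CONTEXT, 150: "K"})
    prot_b = compose_protein(70, {25: "F"})
    prot_c = compose_protein(120, {30: "F", 34: "Y", 60: "F", 64: "Y",
                                   91: "F", 95: "Y", 110: "L"})
    prot_e = compose_protein(60, {10: "F"})
    prot_f5 = compose_protein(60, {40: FUSION_FLANK5})
    prot_f3 = compose_protein(40, {22: FUSION_FLANK3})

    # GENED: wildtype-frame/shifted-frame dual-design block at residue 80.
    # Deleting the block's first two bases shifts the frame onto seven
    # novel codons (AAEGHKP) then a stop; the unshifted frame reads
    # KLQKDINLK with no stop.
    part1 = compose_protein(79)
    fs_block = "AA" + "GCTGCAGAAGGACATAAACCTTAA" + "A"
    rest = (_FILL * 3)[:22]
    cds_d = codons(part1) + fs_block + codons(rest)
    prot_d = translate_to_stop(cds_d + "TAA")
    if prot_d != part1 + "KLQKDINLK" + rest:
        raise GenerationError("frameshift block does not translate as designed")

    # -- genes ----------------------------------------------------------------
    genes = [
        build_gene("GENEA", "chr1", "+", 500, rng, prot_a, utr5=60, utr3=60,
                   intron_after=60 + 150, intron_len=100),
        build_gene("GENEB", "chr1", "-", 1500, rng, prot_b),
        build_gene("GENEC", "chr1", "+", 2000, rng, prot_c, utr5=50, utr3=50),
        build_gene("GENED", "chr1", "+", 2700, rng, prot_d, cds_nt=cds_d),
        build_gene("GENEE", "chr1", "+", 3400, rng, prot_e, utr5=30, utr3=30),
        build_gene("LINC1", "chr1", "+", 4000, rng, biotype="lincRNA", exon_len=300),
        build_gene("IG1", "chr1", "+", 4600, rng, biotype="IG_V_gene", exon_len=200),
        build_gene("IG2", "chr1", "+", 5000, rng, biotype="IG_V_gene", exon_len=200),
        build_gene("FUS5", "chrF5", "+", 300, rng, prot_f5, utr5=50, utr3=50),
        build_gene("FUS3", "chrF3", "+", 300, rng, prot_f3, utr5=50, utr3=50),
        build_gene("FUS3S", "chrF3", "+", 800, rng, compose_protein(16),
                   utr5=30, utr3=60),
        build_gene("RT1", "chr2", "+", 2000, rng, compose_protein(80), utr5=100, utr3=57),
        build_gene("RT2", "chr2", "+", 402_000, rng, compose_protein(80), utr5=100, utr3=57),
        build_gene("RT3", "chr2", "+", 602_000, rng, compose_protein(80), utr5=100, utr3=57),
        build_gene("RT4", "chr2", "+", 502_000, rng, compose_protein(80), utr5=100, utr3=57),
        build_gene("MT1", "chrM", "+", 100, rng, biotype="protein_coding", exon_len=300),
        build_gene("MT2", "chrM", "+", 600, rng, biotype="protein_coding", exon_len=300),
    ]
    for g in genes:
        out.genes[g.name] = g
        chunk = g.genomic_chunk()
        contigs[g.chrom][g.g_start : g.g_start + len(chunk)] = list(chunk)
    # plant the FUS3S early-stop block at the start of its 3' UTR
    f3s = out.genes["FUS3S"]
    utr3_local = 30 + len(codons(f3s.protein)) + 3
    gpos = f3s.g_start + utr3_local
    contigs["chrF3"][gpos : gpos + len(FUSION_STOP_NT)] = list(FUSION_STOP_NT)
    fus3s_bp3 = gpos

    genome = {name: "".join(chars) for name, chars in contigs.items()}

    # consistency self-check: every coding gene translates as designed
    for g in genes:
        if g.protein:
            got = translate_to_stop(g.model.spliced_cds(genome))
            if got != g.protein:
                raise GenerationError(f"{g.name}: CDS does not translate to plan")

    # -- planted SNVs ---------------------------------------------------------
    def plant_snv(gene_name: str, residue: int, to_aa: str, callers: tuple[str, ...],
                  expect: bool, syn: bool = False):
        g = out.genes[gene_name]
        wt_aa = g.protein[residue - 1]
        i, b = snv_encoding(PREF_CODON[wt_aa], to_aa)
        off = (residue - 1) * 3 + i
        gpos = g.model.cds_positions[off]
        if g.strand == "+":
            ref, alt = genome[g.chrom][gpos], b
        else:
            ref, alt = genome[g.chrom][gpos], revcomp(b)
        rec = (g.chrom, gpos + 1, ref, alt)
        status = f"present:{','.join(sorted(callers))}" if expect else "absent"
        out.truth.append(TruthRow("consensus_snv", f"{g.chrom}:{gpos + 1}:{ref}>{alt}", status))
        return rec, off, gpos, syn

    snv_plan = [
        ("GENEA", 133, "V", CALLERS, True, False),
        ("GENEA", 150, "E", ("mutect",), False, False),
        ("GENEB", 25, "C", ("mutect", "radia"), True, False),
        ("GENEC", 30, "V", ("mutect", "muse", "radia"), True, False),
        ("GENEC", 34, "S", ("muse", "radia"), True, False),
        ("GENEC", 60, "V", ("mutect", "sniper"), True, False),
        ("GENEC", 64, "S", ("mutect", "sniper"), True, False),
        ("GENEC", 91, "V", ("muse", "strelka"), True, False),
        ("GENEC", 95, "S", ("muse", "strelka"), True, False),
        ("GENEC", 110, "L", ("mutect", "muse"), True, True),
        ("GENEE", 10, "V", ("mutect", "muse", "radia"), True, False),
    ]
    caller_rows: dict[str, list[tuple]] = {c: [] for c in CALLERS}
    planted: dict[tuple[str, int], dict] = {}
    for gene_name, residue, to_aa, callers, expect, syn in snv_plan:
        rec, off, gpos, _ = plant_snv(gene_name, residue, to_aa, callers, expect, syn)
        planted[(gene_name, residue)] = {
            "rec": rec, "off": off, "gpos": gpos, "to_aa": to_aa, "syn": syn,
        }
        for c in callers:
            caller_rows[c].append(rec)

    # -- planted indels -------------------------------------------------------
    ga = out.genes["GENEA"]
    anchor = ga.model.cds_positions[59]  # insert codon GCT after residue 20
    ins_rec = ("chr1", anchor + 1, genome["chr1"][anchor], genome["chr1"][anchor] + "GCT")
    out.truth.append(TruthRow(
        "consensus_indel", f"chr1:{anchor + 2}:->GCT", f"present:{INDEL_SOURCE}"))

    gd = out.genes["GENED"]
    del_anchor = gd.model.cds_positions[236]  # remove the two fs_block bases
    del_ref = genome["chr1"][del_anchor : del_anchor + 3]
    del_rec = ("chr1", del_anchor + 1, del_ref, del_ref[0])
    out.truth.append(TruthRow(
        "consensus_indel", f"chr1:{del_anchor + 2}:{del_ref[1:]}>-", f"present:{INDEL_SOURCE}"))

    gc = out.genes["GENEC"]
    lowq_anchor = gc.model.cds_positions[150]
    lowq_rec = ("chr1", lowq_anchor + 1, genome["chr1"][lowq_anchor],
                genome["chr1"][lowq_anchor] + "GGG")
    out.truth.append(TruthRow(
        "consensus_indel", f"chr1:{lowq_anchor + 2}:->GGG", "absent"))

    # -- VCF writing ----------------------------------------------------------
    def write_vcf(path: Path, rows: list[tuple], filters: list[str] | None = None):
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FILTER=<ID=LowQual,Description="Low quality">\n')
            for name in sorted(contig_lens):
                fh.write(f"##contig=<ID={name},length={contig_lens[name]}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            filters = filters or ["PASS"] * len(rows)
            for (chrom, pos, ref, alt), filt in sorted(
                zip(rows, filters), key=lambda t: (t[0][0], t[0][1], t[0][3])
            ):
                fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t50\t{filt}\t.\n")

    for caller in CALLERS:
        p = out.outdir / f"snv_{caller}.vcf"
        write_vcf(p, caller_rows[caller])
        out.paths[f"vcf_{caller}"] = p
    indel_path = out.outdir / "indels_strelka.vcf"
    write_vcf(indel_path, [ins_rec, del_rec, lowq_rec], ["PASS", "PASS", "LowQual"])
    out.paths["indel_vcf"] = indel_path

    # -- fusions --------------------------------------------------------------
    def bp_of(gene_name: str, cds_off: int | None = None, at: int | None = None) -> int:
        g = out.genes[gene_name]
        return g.model.cds_positions[cds_off] if cds_off is not None else at

    bp_fus5 = bp_of("FUS5", 48 * 3 - 1)       # junction after residue 48
    bp_fus5_b = bp_of("FUS5", 47 * 3 - 1)     # one codon earlier
    bp_fus3 = bp_of("FUS3", (22 - 1) * 3)     # start of EALSVVSED block
    intron_iv = (ga.model.exons[0][1], ga.model.exons[1][0])
    bp_intron = intron_iv[0] + 40
    b1, b2, b3, b4 = 2050, 402_050, 602_050, 502_050
    bp_linc = out.genes["LINC1"].g_start + 100
    bp_mt1 = out.genes["MT1"].g_start + 50
    bp_mt2 = out.genes["MT2"].g_start + 50
    bp_ig1 = out.genes["IG1"].g_start + 50
    bp_ig2 = out.genes["IG2"].g_start + 50

    # (name, chrom5, bp5, chrom3, bp3, support, expected)
    fusion_plan = [
        ("FUS5--FUS3", "chrF5", bp_fus5, "chrF3", bp_fus3, spec.fusion_support, "kept_iar"),
        ("FUS5--FUS3S", "chrF5", bp_fus5, "chrF3", fus3s_bp3, 9, "kept_iar"),
        ("FUS5--FUS3", "chrF5", bp_fus5_b, "chrF3", bp_fus3, 4, "kept_iar"),
        ("RT1--RT3", "chr2", b1, "chr2", b3, 6, "kept_no_iar:utr_5p"),
        ("RT1--RT2", "chr2", b1, "chr2", b2, 5, "readthrough"),
        ("RT1--RT4", "chr2", b1, "chr2", b4, 5, "readthrough"),
        ("RT2--RT3", "chr2", b2, "chr2", b3, 5, "readthrough"),
        ("RT4--RT1", "chr2", b4, "chr2", b1, 3, "readthrough"),
        ("MT1--MT2", "chrM", bp_mt1, "chrM", bp_mt2, 8, "mito_mito"),
        ("MT2--MT1", "chrM", bp_mt2, "chrM", bp_mt1, 8, "mito_mito"),
        ("IG1--IG2", "chr1", bp_ig1, "chr1", bp_ig2, 7, "ig_ig"),
        ("IG2--IG1", "chr1", bp_ig2, "chr1", bp_ig1, 7, "ig_ig"),
        ("LINC1--FUS3", "chr1", bp_linc, "chrF3", bp_fus3, 4, "linc_5p"),
        ("LINC1--FUS3S", "chr1", bp_linc, "chrF3", fus3s_bp3, 4, "linc_5p"),
        ("LINC1--RT2", "chr1", bp_linc, "chr2", b2, 2, "linc_5p"),
        ("GHOSTA--FUS3", "chr1", 100, "chrF3", bp_fus3, 2, "unresolved_gene"),
        ("FUS5--GHOSTB", "chrF5", bp_fus5, "chr1", 100, 2, "unresolved_gene"),
        ("GENEA--FUS3", "chr1", bp_intron, "chrF3", bp_fus3, 3, "kept_no_iar:intronic_5p"),
        ("IG1--MT1", "chr1", bp_ig1, "chrM", bp_mt1, 2, "kept_no_iar:utr_5p"),
        ("MT1--IG2", "chrM", bp_mt1, "chr1", bp_ig2, 2, "kept_no_iar:utr_5p"),
    ]
    bedpe_path = out.outdir / "fusions.bedpe"
    with open(bedpe_path, "w") as fh:
        for name, c5, bp5, c3, bp3, support, expected in fusion_plan:
            fh.write("\t".join(map(str, [
                c5, bp5, bp5 + 1, c3, bp3, bp3 + 1, name, support, "+", "+",
            ])) + "\n")
            key = f"{name}:{c5}:{bp5 + 1}:{c3}:{bp3 + 1}"
            out.truth.append(TruthRow("fusion", key, expected))
    out.paths["bedpe"] = bedpe_path

    # -- expected IAR peptides ------------------------------------------------
    def plant_iar_truth(label: str, wt: str, mut: str, indices: list[int],
                        frameshift: bool = False, absent: bool = False):
        for n in (9, 10, 15):
            pep, _ = _window(wt, mut, indices, n, frameshift)
            cat = "iar_absent" if absent else "iar"
            out.truth.append(TruthRow(cat, f"{label}:{n}", pep))

    def sub(wt: str, residue_to_aa: dict[int, str]) -> tuple[str, list[int]]:
        seq = list(wt)
        for r, aa in residue_to_aa.items():
            seq[r - 1] = aa
        return "".join(seq), [r - 1 for r in residue_to_aa]

    mut, idx = sub(prot_a, {133: "V"})
    plant_iar_truth("GENEA_F133V", prot_a, mut, idx)
    mut, idx = sub(prot_b, {25: "C"})
    plant_iar_truth("GENEB_F25C", prot_b, mut, idx)
    mut, idx = sub(prot_c, {30: "V", 34: "S"})
    plant_iar_truth("GENEC_cis_pair", prot_c, mut, idx)
    for r, aa in ((60, "V"), (64, "S"), (91, "V"), (95, "S")):
        mut, idx = sub(prot_c, {r: aa})
        plant_iar_truth(f"GENEC_single_{r}", prot_c, mut, idx)
    mut, idx = sub(prot_c, {60: "V", 64: "S"})
    plant_iar_truth("GENEC_trans_joint", prot_c, mut, idx, absent=True)
    mut, idx = sub(prot_c, {91: "V", 95: "S"})
    plant_iar_truth("GENEC_nocov_joint", prot_c, mut, idx, absent=True)
    mut, idx = sub(prot_e, {10: "V"})
    plant_iar_truth("GENEE_unexpressed", prot_e, mut, idx, absent=True)

    ins_mut = prot_a[:20] + "A" + prot_a[20:]
    plant_iar_truth("GENEA_ins21A", prot_a, ins_mut, [20])
    fs_mut = prot_d[:79] + "AAEGHKP"
    plant_iar_truth("GENED_frameshift", prot_d, fs_mut, list(range(79, 86)),
                    frameshift=True)

    for n in (9, 10, 15):
        flank5 = prot_f5[48 - min(48, n - 1) : 48]
        flank5_b = prot_f5[47 - min(47, n - 1) : 47]
        down = (FUSION_FLANK3 + (_FILL * 3)[9:])[: n - 1]
        out.truth.append(TruthRow("iar", f"FUSION_main:{n}", flank5 + down))
        out.truth.append(TruthRow("iar", f"FUSION_shift:{n}", flank5_b + down))
        out.truth.append(TruthRow("iar", f"FUSION_stop:{n}", flank5 + "ELS"))

    # -- expression -----------------------------------------------------------
    expr_path = out.outdir / "expression.tsv"
    with open(expr_path, "w") as fh:
        fh.write("transcript_id\tgene_id\ttpm\n")
        for name in sorted(out.genes):
            fh.write(f"{name}.t1\t{name}\t{spec.tpm.get(name, 1.0)}\n")
    out.paths["expression"] = expr_path

    # -- HLA call lists -------------------------------------------------------
    base_alleles = [
        "HLA-A*02:01", "HLA-A*01:01", "HLA-B*07:02", "HLA-B*44:02",
        "HLA-C*07:01", "HLA-C*07:02", "HLA-DRB1*15:01", "HLA-DRB1*07:01",
        "HLA-DPA1*01:03", "HLA-DPB1*04:01",
    ]
    hla_sources = {
        "tumor_dna": base_alleles + ["HLA-DQB1*06:02"],
        "normal_dna": ["HLA-A*01:81" if a == "HLA-A*02:01" else a for a in base_alleles]
        + ["HLA-DQB1*06:02"],
        "tumor_rna": [a for a in base_alleles if a != "HLA-C*07:02"],
    }
    for source, alleles in hla_sources.items():
        p = out.outdir / f"hla_{source}.txt"
        with open(p, "w") as fh:
            fh.write("\n".join(alleles) + "\n")
        out.paths[f"hla_{source}"] = p
    for a in base_alleles:
        out.truth.append(TruthRow("hla", a, "present"))
    out.truth.append(TruthRow("hla", "HLA-A*01:81", "absent"))
    out.truth.append(TruthRow("hla", "HLA-DQB1*06:02", "absent"))

    # -- phasing RNA reads ----------------------------------------------------
    def read_seq(chrom: str, start: int, alts: dict[int, str]) -> str:
        seq = list(genome[chrom][start : start + spec.read_len])
        for gpos, b in alts.items():
            seq[gpos - start] = b
        return "".join(seq)

    cis1 = planted[("GENEC", 30)]
    cis2 = planted[("GENEC", 34)]
    tr1 = planted[("GENEC", 60)]
    tr2 = planted[("GENEC", 64)]
    reads: list[tuple[str, str, int, str]] = []  # (qname, chrom, start, seq)
    start = cis1["gpos"] - 15
    both = {cis1["gpos"]: cis1["rec"][3], cis2["gpos"]: cis2["rec"][3]}
    for i in range(5):
        reads.append((f"cis_{i}", "chr1", start, read_seq("chr1", start, both)))
    tstart = tr1["gpos"] - 15
    t_both = {tr1["gpos"]: tr1["rec"][3], tr2["gpos"]: tr2["rec"][3]}
    reads.append(("tr_both", "chr1", tstart, read_seq("chr1", tstart, t_both)))
    for i in range(2):
        reads.append((f"tr_a1_{i}", "chr1", tstart,
                      read_seq("chr1", tstart, {tr1["gpos"]: tr1["rec"][3]})))
    reads.append(("tr_a2", "chr1", tstart,
                  read_seq("chr1", tstart, {tr2["gpos"]: tr2["rec"][3]})))

    out.truth.append(TruthRow(
        "phase", f"chr1:{cis1['gpos'] + 1}:{cis2['gpos'] + 1}", "joined"))
    out.truth.append(TruthRow(
        "phase", f"chr1:{tr1['gpos'] + 1}:{tr2['gpos'] + 1}", "split"))
    nc1 = planted[("GENEC", 91)]
    nc2 = planted[("GENEC", 95)]
    out.truth.append(TruthRow(
        "phase", f"chr1:{nc1['gpos'] + 1}:{nc2['gpos'] + 1}", "split"))

    sam_path = out.outdir / "rna.sam"
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": contig_lens[name]} for name in sorted(contig_lens)],
    })
    ref_ids = {name: i for i, name in enumerate(sorted(contig_lens))}
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as sam:
        for qname, chrom, rstart, seq in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = qname
            a.query_sequence = seq
            a.flag = 0
            a.reference_id = ref_ids[chrom]
            a.reference_start = rstart
            a.mapping_quality = 60
            a.cigarstring = f"{len(seq)}M"
            sam.write(a)
        unmapped = pysam.AlignedSegment(header)
        unmapped.query_name = "unmapped_1"
        unmapped.query_sequence = "ACGT" * 10
        unmapped.flag = 4
        sam.write(unmapped)
    out.paths["rna_sam"] = sam_path

    # -- genome FASTA and GTF -------------------------------------------------
    fasta_path = out.outdir / "genome.fa"
    with open(fasta_path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    out.paths["fasta"] = fasta_path

    gtf_path = out.outdir / "annotation.gtf"
    with open(gtf_path, "w") as fh:
        for g in genes:
            m = g.model
            attrs = (
                f'gene_id "{g.name}"; transcript_id "{m.transcript_id}"; '
                f'gene_type "{g.biotype}"; gene_name "{g.name}";'
            )
            s, e = m.span
            fh.write(f"{g.chrom}\ttoy\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")
            fh.write(f"{g.chrom}\ttoy\ttranscript\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")
            for xs, xe in m.exons:
                fh.write(f"{g.chrom}\ttoy\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t{attrs}\n")
            cum = 0
            cds_tx_order = m.cds if g.strand == "+" else list(reversed(m.cds))
            for cs, ce in cds_tx_order:
                frame = (3 - cum % 3) % 3
                fh.write(f"{g.chrom}\ttoy\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t{frame}\t{attrs}\n")
                cum += ce - cs
    out.paths["gtf"] = gtf_path

    # -- truth table ----------------------------------------------------------
    truth_path = out.outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("category\tkey\texpected\n")
        for row in out.truth:
            fh.write(f"{row.category}\t{row.key}\t{row.expected}\n")
    out.paths["truth"] = truth_path

    return out


# ---------------------------------------------------------------------------
# truth checking
# ---------------------------------------------------------------------------

@dataclass
class TruthReport:
    n_checks: int = 0
    failures: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def read_truth(path) -> list[TruthRow]:
    rows = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            cat, key, expected = line.rstrip("\n").split("\t")
            rows.append(TruthRow(cat, key, expected))
    return rows


def truth_check(result, truth_path) -> TruthReport:
    """Compare pipeline output against the planted truth table.

    ``result`` is a :class:`~neopept.pipeline.PipelineResult`. Peptide
    comparisons are exact string matches.
    """
    rows = read_truth(truth_path)
    report = TruthReport()

    cons = {}
    for v in result.consensus_variants:
        key = f"{v.chrom}:{v.vcf_pos}:{v.ref or '-'}>{v.alt or '-'}"
        cons[key] = ",".join(sorted(v.supporting_callers))
    rejections = {key: reasons for key, reasons in result.fusion_rejections}
    phase = {
        f"{chrom}:{p1}:{p2}": ("joined" if joined else "split")
        for chrom, p1, p2, joined in result.phase_records
    }
    peptides_by_n: dict[int, set[str]] = {9: set(), 10: set(), 15: set()}
    for iar in result.iars:
        for n in (9, 10, 15):
            pep = iar.mutant_peptide(n)
            if pep:
                peptides_by_n[n].add(pep)

    for row in rows:
        report.n_checks += 1
        ok, detail = True, ""
        if row.category in ("consensus_snv", "consensus_indel"):
            if row.expected == "absent":
                ok = row.key not in cons
                detail = f"unexpectedly present ({cons.get(row.key)})"
            else:
                want = row.expected.removeprefix("present:")
                ok = cons.get(row.key) == want
                detail = f"got {cons.get(row.key)!r}, want {want!r}"
        elif row.category == "hla":
            present = row.key in result.haplotype.alleles
            ok = present == (row.expected == "present")
            detail = f"allele presence is {present}"
        elif row.category == "fusion":
            if row.expected == "kept_iar":
                ok = row.key not in rejections
                detail = f"rejected with {rejections.get(row.key)}"
            elif row.expected.startswith("kept_no_iar:"):
                want = row.expected.split(":", 1)[1]
                ok = want in rejections.get(row.key, [])
                detail = f"got {rejections.get(row.key)}"
            else:
                ok = row.expected in rejections.get(row.key, [])
                detail = f"got {rejections.get(row.key)}"
        elif row.category == "phase":
            ok = phase.get(row.key) == row.expected
            detail = f"got {phase.get(row.key)}"
        elif row.category == "iar":
            n = int(row.key.rsplit(":", 1)[1])
            ok = row.expected in peptides_by_n[n]
            detail = "peptide missing"
        elif row.category == "iar_absent":
            n = int(row.key.rsplit(":", 1)[1])
            ok = row.expected not in peptides_by_n[n]
            detail = "peptide unexpectedly present"
        if not ok:
            report.failures.append(f"{row.category} {row.key}: {detail}")
    return report
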