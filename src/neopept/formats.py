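"""Readers and writers for every external format the pipeline touches.

Coordinate conventions are strict: VCF positions are 1-based inclusive on
disk and converted to the package's uniform 0-based half-open convention
only where downstream code needs it; BEDPE intervals are 0-based half-open
as defined by the format; GTF 1-based inclusive intervals are converted to
0-based half-open on ingestion.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd
import pysam

from .errors import FormatError, RecordError
from .transcript import TranscriptModel

log = logging.getLogger(__name__)

_DNA = set("ACGT")

CLASS_I_LOCI = {"A", "B", "C"}
CLASS_II_LOCI = {"DPA", "DPB", "DRB"}
KEPT_LOCI = CLASS_I_LOCI | CLASS_II_LOCI

_ALLELE_RE = re.compile(r"^HLA-([A-Z]+\d*)\*(\d{2,3}):(\d{2,3})$")


@dataclass(frozen=True)
class VariantRecord:
    """One ALT allele of one VCF row, as called by one caller."""

    chrom: str
    pos: int  # 1-based, as in the VCF
    ref: str
    alt: str
    caller: str
    passed: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise RecordError(f"position {self.pos} < 1 at {self.chrom}")
        for allele in (self.ref, self.alt):
            if not allele or set(allele) - _DNA:
                raise RecordError(
                    f"allele {allele!r} at {self.chrom}:{self.pos} is not plain DNA"
                )
        if self.ref == self.alt:
            raise RecordError(f"ref == alt at {self.chrom}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class FusionRecord:
    """A candidate fusion junction from a BEDPE row.

    The junction base convention (which side is inclusive) is resolved by
    :meth:`breakpoint5` / :meth:`breakpoint3`: for a ``+`` 5' partner the
    junction-adjacent base is ``end5 - 1`` (end exclusive); for a ``+`` 3'
    partner it is ``start3`` (start inclusive); minus-strand partners use
    the strand-symmetric opposite ends.
    """

    chrom5: str
    start5: int
    end5: int
    chrom3: str
    start3: int
    end3: int
    name: str
    support: int
    strand5: str = "+"
    strand3: str = "+"
    junction_seq5: str | None = None
    junction_seq3: str | None = None

    def __post_init__(self) -> None:
        if self.start5 >= self.end5 or self.start3 >= self.end3:
            raise RecordError(f"reversed interval in fusion {self.name}")
        if self.support < 0:
            raise RecordError(f"negative support in fusion {self.name}")

    @property
    def gene5(self) -> str:
        return _split_fusion_name(self.name)[0]

    @property
    def gene3(self) -> str:
        return _split_fusion_name(self.name)[1]

    @property
    def breakpoint5(self) -> int:
        """Genomic position of the last transcribed base of the 5' partner."""
        return self.end5 - 1 if self.strand5 == "+" else self.start5

    @property
    def breakpoint3(self) -> int:
        """Genomic position of the first transcribed base of the 3' partner."""
        return self.start3 if self.strand3 == "+" else self.end3 - 1

    @property
    def key(self) -> str:
        return (
            f"{self.name}:{self.chrom5}:{self.breakpoint5 + 1}:"
            f"{self.chrom3}:{self.breakpoint3 + 1}"
        )


def _split_fusion_name(name: str) -> tuple[str, str]:
    for sep in ("--", ">>"):
        if sep in name:
            a, b = name.split(sep, 1)
            return a, b
    raise RecordError(f"fusion name {name!r} has no '--' or '>>' separator")


@dataclass(frozen=True)
class ExpressionRecord:
    transcript_id: str
    gene_id: str
    tpm: float

    def __post_init__(self) -> None:
        if self.tpm < 0:
            raise RecordError(f"negative TPM for {self.transcript_id}")


@dataclass
class HaplotypeCallSet:
    """MHC allele calls from one sequencing source."""

    source: str
    alleles: list[str] = field(default_factory=list)


def parse_hla_allele(name: str) -> tuple[str, str]:
    """Return (locus_family, normalized_name); raises RecordError if unparseable.

    The locus family collapses numbered genes onto their group, e.g.
    DRB1 -> DRB, DPA1 -> DPA, so the retained-locus filter can operate on
    the families the pipeline supports.
    """
    m = _ALLELE_RE.match(name.strip())
    if not m:
        raise RecordError(f"unparseable HLA allele {name!r}")
    locus = m.group(1)
    for fam in sorted(KEPT_LOCI, key=len, reverse=True):
        if locus.startswith(fam):
            return fam, name.strip()
    return locus, name.strip()


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_vcf(path, caller: str) -> list[VariantRecord]:
    """Read one caller's VCF; multi-allelic rows are split per ALT allele.

    Symbolic/non-ACGT alleles and rows where REF equals ALT are skipped
    with a logged warning.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: not a readable VCF: {exc}") from None
    records: list[VariantRecord] = []
    skipped = 0
    for rec in vf:
        if rec.pos < 1:
            raise RecordError(f"{path}: coordinate {rec.pos} < 1")
        filters = list(rec.filter.keys())
        passed = not filters or filters == ["PASS"]
        for alt in rec.alts or ():
            ref = (rec.ref or "").upper()
            alt = alt.upper()
            if not ref or not alt or set(ref) - _DNA or set(alt) - _DNA or ref == alt:
                skipped += 1
                continue
            records.append(
                VariantRecord(rec.chrom, rec.pos, ref, alt, caller, passed)
            )
    if skipped:
        log.warning("%s: skipped %d symbolic/degenerate ALT records", path, skipped)
    return records


def read_bedpe(path) -> list[FusionRecord]:
    """Read fusion calls from a 10+ column BEDPE.

    Columns 11 and 12, when present and non-empty, are taken as the
    junction-flanking nucleotide sequences (5' flank ending at the
    junction, 3' flank starting at it).
    """
    fusions: list[FusionRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 10:
                raise FormatError(f"{path}:{ln}: BEDPE needs >= 10 columns, got {len(cols)}")
            seq5 = cols[10].upper() if len(cols) > 10 and cols[10] not in ("", ".") else None
            seq3 = cols[11].upper() if len(cols) > 11 and cols[11] not in ("", ".") else None
            fusions.append(
                FusionRecord(
                    chrom5=cols[0], start5=int(cols[1]), end5=int(cols[2]),
                    chrom3=cols[3], start3=int(cols[4]), end3=int(cols[5]),
                    name=cols[6], support=int(cols[7]),
                    strand5=cols[8], strand3=cols[9],
                    junction_seq5=seq5, junction_seq3=seq3,
                )
            )
    return fusions


def read_gtf(path) -> list[TranscriptModel]:
    """Parse a GENCODE-dialect GTF into transcript models.

    Intervals are converted to 0-based half-open. Unknown attributes are
    ignored. A CDS whose transcript_id has no transcript feature, or
    overlapping CDS segments within one transcript, are format errors.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
    except Exception as exc:  # noqa: BLE001 - sqlite/parse failures alike
        raise FormatError(f"{path}: cannot parse GTF: {exc}") from None

    transcripts: dict[str, dict] = {}
    order: list[str] = []
    for f in db.all_features():
        if f.featuretype not in {"transcript", "exon", "CDS"}:
            continue
        tid = f.attributes.get("transcript_id", [None])[0]
        if tid is None:
            continue
        entry = transcripts.setdefault(tid, {"transcript": None, "exons": [], "cds": []})
        if f.featuretype == "transcript":
            entry["transcript"] = f
            order.append(tid)
        elif f.featuretype == "exon":
            entry["exons"].append((f.start - 1, f.end))
        else:
            entry["cds"].append((f.start - 1, f.end))

    models: list[TranscriptModel] = []
    for tid in order:
        entry = transcripts[tid]
        feat = entry["transcript"]
        attrs = feat.attributes
        biotype = (attrs.get("gene_type") or attrs.get("gene_biotype") or ["unknown"])[0]
        cds = sorted(entry["cds"])
        for (s1, e1), (s2, e2) in zip(cds, cds[1:]):
            if s2 < e1:
                raise FormatError(f"{path}: overlapping CDS segments in {tid}")
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=attrs.get("gene_id", [""])[0],
                gene_name=attrs.get("gene_name", attrs.get("gene_id", [""]))[0],
                biotype=biotype,
                chrom=feat.seqid,
                strand=feat.strand,
                exons=sorted(entry["exons"]),
                cds=cds,
            )
        )
    orphans = [tid for tid, e in transcripts.items() if e["transcript"] is None and e["cds"]]
    if orphans:
        raise FormatError(f"{path}: CDS without parent transcript: {orphans}")
    return models


def read_expression(path) -> pd.DataFrame:
    """Read an isoform expression table (transcript_id, gene_id, tpm).

    Rows with negative TPM are dropped with a warning; a duplicated
    transcript_id is a format error. Returns a DataFrame indexed by
    transcript_id.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "gene_id", "tpm"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expression table needs columns {sorted(required)}")
    bad = df["tpm"] < 0
    if bad.any():
        log.warning("%s: dropped %d rows with negative TPM", path, int(bad.sum()))
        df = df[~bad]
    if df["transcript_id"].duplicated().any():
        dups = df.loc[df["transcript_id"].duplicated(), "transcript_id"].tolist()
        raise FormatError(f"{path}: duplicate transcript_id {dups}")
    return df.set_index("transcript_id")


def expression_lookup(expression: pd.DataFrame | None):
    """Return a TPM lookup function; missing transcripts count as 0."""
    if expression is None:
        return lambda tid: 0.0
    tpm = expression["tpm"]
    return lambda tid: float(tpm.get(tid, 0.0))


def read_haplotype_list(path, source: str) -> HaplotypeCallSet:
    """Read a plain-text allele list (one allele per line) for one source."""
    alleles: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                _, name = parse_hla_allele(line)
            except RecordError as exc:
                raise RecordError(f"{path} (source {source}): {exc}") from None
            alleles.append(name)
    return HaplotypeCallSet(source=source, alleles=alleles)


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------

IAR_REPORT_COLUMNS = [
    "final_position", "iar_id", "source_type",
    "peptide_9", "peptide_10", "peptide_15",
    "npa", "nph", "nmhc", "tpm", "nwt", "ovlp", "boost",
    "initial_position", "wt_9", "wt_10", "wt_15",
]

EPITOPE_COLUMNS = ["iar_id", "n", "peptide", "allele", "mut_rank", "wt_peptide", "wt_rank"]


def _opt(value) -> str:
    return "" if value is None else str(value)


def write_iar_report(ranked, path) -> None:
    """Write the final ranked-IAR report as a TSV with a fixed column order."""
    rows = []
    for r in ranked:
        f = r.features
        pep = r.peptides or {}
        wt = r.wt_peptides or {}
        rows.append({
            "final_position": r.final_position,
            "iar_id": r.iar_id,
            "source_type": r.source_type,
            "peptide_9": _opt(pep.get(9)),
            "peptide_10": _opt(pep.get(10)),
            "peptide_15": _opt(pep.get(15)),
            "npa": f.npa, "nph": f.nph, "nmhc": f.nmhc,
            "tpm": repr(f.tpm), "nwt": f.nwt, "ovlp": f.ovlp,
            "boost": repr(r.boost),
            "initial_position": r.initial_position,
            "wt_9": _opt(wt.get(9)), "wt_10": _opt(wt.get(10)), "wt_15": _opt(wt.get(15)),
        })
    pd.DataFrame(rows, columns=IAR_REPORT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_iar_report(path):
    """Read back a ranked-IAR report; inverse of :func:`write_iar_report`."""
    from .rankboost import IARFeatures, RankedIAR

    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    ranked = []
    for _, row in df.iterrows():
        feats = IARFeatures(
            npa=int(row["npa"]), nph=int(row["nph"]), nmhc=int(row["nmhc"]),
            tpm=float(row["tpm"]), nwt=int(row["nwt"]), ovlp=int(row["ovlp"]),
        )
        peptides = {n: row[f"peptide_{n}"] for n in (9, 10, 15) if row[f"peptide_{n}"]}
        wt = {n: row[f"wt_{n}"] for n in (9, 10, 15) if row[f"wt_{n}"]}
        ranked.append(RankedIAR(
            iar_id=row["iar_id"], features=feats, boost=float(row["boost"]),
            initial_position=int(row["initial_position"]),
            final_position=int(row["final_position"]),
            source_type=row["source_type"], peptides=peptides, wt_peptides=wt,
        ))
    return ranked


def write_epitope_table(calls, path) -> None:
    rows = [{
        "iar_id": c.iar_id, "n": len(c.peptide), "peptide": c.peptide,
        "allele": c.allele, "mut_rank": repr(c.mut_rank),
        "wt_peptide": _opt(c.wt_peptide),
        "wt_rank": "" if c.wt_rank is None else repr(c.wt_rank),
    } for c in calls]
    pd.DataFrame(rows, columns=EPITOPE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_epitope_table(path):
    from .binding import EpitopeCall

    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    return [
        EpitopeCall(
            iar_id=row["iar_id"], peptide=row["peptide"], allele=row["allele"],
            mut_rank=float(row["mut_rank"]),
            wt_peptide=row["wt_peptide"] or None,
            wt_rank=float(row["wt_rank"]) if row["wt_rank"] else None,
        )
        for _, row in df.iterrows()
    ]
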