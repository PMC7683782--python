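"""Consensus merging of somatic calls and HLA haplotypes.

SNVs from multiple callers are merged on the exact normalized
(chrom, pos, ref, alt) key and advance only when two or more callers
agree. Short insertions/deletions come from a single dedicated source and
pass through without a consensus requirement. The consensus HLA haplotype
keeps every allele called by at least two of the three sequencing sources.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .errors import RecordError
from .formats import (
    CLASS_I_LOCI,
    KEPT_LOCI,
    HaplotypeCallSet,
    VariantRecord,
    parse_hla_allele,
)

log = logging.getLogger(__name__)

#: the single caller trusted for short insertions/deletions
INDEL_SOURCE = "strelka"


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix then prefix; returns minimal (pos, ref, alt).

    ``pos`` keeps the incoming coordinate base (1-based VCF in, 1-based
    out). Either trimmed allele may be empty (pure insertion/deletion).
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass(frozen=True)
class ConsensusVariant:
    """A somatic event with its supporting-caller set.

    ``pos`` is internal 0-based; ``ref``/``alt`` are minimal trimmed
    alleles (one may be empty for a pure indel).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    supporting_callers: frozenset[str]
    kind: str  # snv | insertion | deletion

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def vcf_pos(self) -> int:
        return self.pos + 1

    @property
    def end(self) -> int:
        """End (exclusive) of the reference footprint; pos for insertions."""
        return self.pos + len(self.ref)


def _normalize(record: VariantRecord) -> tuple[str, int, str, str]:
    pos, ref, alt = trim_alleles(record.pos, record.ref, record.alt)
    return (record.chrom, pos - 1, ref, alt)


def merge_snv_calls(
    calls_by_caller: dict[str, list[VariantRecord]],
    min_support: int = 2,
    require_pass: bool = True,
) -> list[ConsensusVariant]:
    """Merge per-caller SNV calls; keep events supported by >= min_support callers."""
    if not calls_by_caller:
        raise RecordError("merge_snv_calls needs at least one caller")
    support: dict[tuple, set[str]] = defaultdict(set)
    for caller in sorted(calls_by_caller):
        seen: set[tuple] = set()
        for rec in calls_by_caller[caller]:
            if not rec.is_snv:
                log.warning("%s: non-SNV %s:%d %s>%s ignored in SNV merge",
                            caller, rec.chrom, rec.pos, rec.ref, rec.alt)
                continue
            if require_pass and not rec.passed:
                continue
            key = _normalize(rec)
            if key in seen:
                log.warning("%s: duplicate record at %s:%d counted once",
                            caller, rec.chrom, rec.pos)
                continue
            seen.add(key)
            support[key].add(caller)
    out = [
        ConsensusVariant(chrom, pos, ref, alt, frozenset(callers), "snv")
        for (chrom, pos, ref, alt), callers in support.items()
        if len(callers) >= min_support
    ]
    out.sort(key=lambda v: (v.chrom, v.pos, v.alt))
    return out


def extract_indels(
    indel_calls: list[VariantRecord], require_pass: bool = True
) -> list[ConsensusVariant]:
    """Pass through filter-passing indels from the single indel source."""
    out: list[ConsensusVariant] = []
    seen: set[tuple] = set()
    for rec in indel_calls:
        if rec.is_snv:
            log.warning("indel source produced SNV at %s:%d; belongs on the SNV path",
                        rec.chrom, rec.pos)
            continue
        if require_pass and not rec.passed:
            continue
        chrom, pos, ref, alt = _normalize(rec)
        if (chrom, pos, ref, alt) in seen:
            continue
        seen.add((chrom, pos, ref, alt))
        kind = "insertion" if len(alt) > len(ref) else "deletion"
        out.append(ConsensusVariant(chrom, pos, ref, alt, frozenset({rec.caller}), kind))
    out.sort(key=lambda v: (v.chrom, v.pos, v.alt))
    return out


@dataclass
class ConsensusHaplotype:
    """Alleles agreed by >= 2 of 3 sources, with MHC class labels."""

    alleles: dict[str, str] = field(default_factory=dict)  # allele name -> class

    def class_alleles(self, mhc_class: str) -> list[str]:
        return sorted(a for a, c in self.alleles.items() if c == mhc_class)


def consensus_haplotype(sources: list[HaplotypeCallSet]) -> ConsensusHaplotype:
    """2-of-3 vote over per-source allele calls.

    Homozygous (duplicated) calls within one source count once toward the
    vote; loci outside the supported families are dropped.
    """
    if len(sources) != 3:
        raise RecordError(f"expected 3 haplotype sources, got {len(sources)}")
    votes: dict[str, set[str]] = defaultdict(set)
    locus_of: dict[str, str] = {}
    for src in sources:
        for raw in src.alleles:
            try:
                fam, name = parse_hla_allele(raw)
            except RecordError as exc:
                raise RecordError(f"source {src.source}: {exc}") from None
            votes[name].add(src.source)
            locus_of[name] = fam
    consensus = ConsensusHaplotype()
    for name in sorted(votes):
        fam = locus_of[name]
        if fam not in KEPT_LOCI:
            continue
        if len(votes[name]) >= 2:
            consensus.alleles[name] = "I" if fam in CLASS_I_LOCI else "II"
    return consensus


# ---------------------------------------------------------------------------
# stage-file serialization (consensus TSV / allele list)
# ---------------------------------------------------------------------------

CONSENSUS_COLUMNS = ["chrom", "pos", "ref", "alt", "kind", "callers"]


def write_consensus_variants(variants: list[ConsensusVariant], path) -> None:
    rows = [{
        "chrom": v.chrom, "pos": v.vcf_pos, "ref": v.ref or "-", "alt": v.alt or "-",
        "kind": v.kind, "callers": ",".join(sorted(v.supporting_callers)),
    } for v in variants]
    pd.DataFrame(rows, columns=CONSENSUS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_consensus_variants(path) -> list[ConsensusVariant]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    return [
        ConsensusVariant(
            chrom=row["chrom"], pos=int(row["pos"]) - 1,
            ref="" if row["ref"] == "-" else row["ref"],
            alt="" if row["alt"] == "-" else row["alt"],
            supporting_callers=frozenset(row["callers"].split(",")),
            kind=row["kind"],
        )
        for _, row in df.iterrows()
    ]


def write_haplotype(haplotype: ConsensusHaplotype, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(haplotype.alleles):
            fh.write(f"{name}\t{haplotype.alleles[name]}\n")


def read_haplotype(path) -> ConsensusHaplotype:
    hap = ConsensusHaplotype()
    with open(path) as fh:
        for line in fh:
            if line.strip():
                name, cls = line.rstrip("\n").split("\t")
                hap.alleles[name] = cls
    return hap
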