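"""Independent oracles and toy-locus builders used across the test suite.

The oracles deliberately re-derive expected results through a different
route than the implementation: whole-string Biopython translation of a
manually edited CDS, and a literal re-execution of the boosting
pseudocode with hand-rolled tied ranks.
"""
from __future__ import annotations

import random
from dataclasses import dataclass

import pysam
from Bio.Seq import Seq

from neopept.consensus import ConsensusVariant
from neopept.fixtures import build_gene
from neopept.transgene import CodingEffect

AA = "ARNDCQEGHILKMFPSTWYV"
CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
STOP_CODONS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]


def toy_locus(protein, strand="+", intron_after=None, g_start=100, seed=1,
              utr5=30, utr3=60, tail=400):
    """One-gene locus: returns (model, genome dict, layout dict)."""
    rng = random.Random(seed)
    gene = build_gene("G1", "chr1", strand, g_start, rng, protein,
                      utr5=utr5, utr3=utr3, intron_after=intron_after)
    prefix = "".join(rng.choices("ACGT", k=g_start))
    suffix = "".join(rng.choices("ACGT", k=tail))
    genome = {"chr1": prefix + gene.genomic_chunk() + suffix}
    cds = gene.model.spliced_cds(genome)
    if strand == "+":
        downstream = genome["chr1"][gene.model.cds[-1][1] :]
        # exonic (3' UTR) part first, then past the gene end: identical
        # concatenation for a last-exon CDS end
    else:
        end = gene.model.cds[0][0]
        downstream = str(Seq(genome["chr1"][:end]).reverse_complement())
    layout = {"cds": cds, "downstream": downstream, "gene": gene}
    return gene.model, genome, layout


def random_coding_locus(rng: random.Random):
    """Random plus-strand locus (sometimes spliced) for translation oracles."""
    n_codons = rng.randint(25, 60)
    protein = "M" + "".join(rng.choices(AA, k=n_codons - 1))
    intron_after = None
    utr5 = rng.randint(10, 40)
    if rng.random() < 0.5:
        intron_after = utr5 + 3 * rng.randint(3, n_codons - 3)
    return toy_locus(protein, strand="+", intron_after=intron_after,
                     seed=rng.randint(0, 2**30), utr5=utr5)


def cds_effect(model, off, ref, alt, genome) -> CodingEffect:
    """A CodingEffect for a CDS-coordinate edit on a plus-strand model."""
    shift = len(alt) - len(ref)
    if ref and alt and len(ref) == len(alt) == 1:
        kind, cls = "snv", "missense"
    elif shift % 3 == 0:
        kind = "insertion" if shift > 0 else "deletion"
        cls = "inframe_ins" if shift > 0 else "inframe_del"
    else:
        kind = "insertion" if shift > 0 else "deletion"
        cls = "frameshift"
    gpos = model.cds_positions[off]
    variant = ConsensusVariant(model.chrom, gpos, ref, alt, frozenset({"test"}), kind)
    return CodingEffect(variant, model.transcript_id, off, cls, "X", "X", ref, alt)


def random_edits(rng: random.Random, model, genome) -> list[CodingEffect]:
    """1-3 non-overlapping random CDS edits (SNV / in-frame / frameshift)."""
    cds = model.spliced_cds(genome)
    usable = len(cds) - 9
    k = rng.randint(1, 3)
    offsets = sorted(rng.sample(range(3, usable, 7), k))
    edits = []
    for off in offsets:
        kind = rng.choice(["snv", "snv", "inframe_ins", "inframe_del", "fs_del", "fs_ins"])
        if kind == "snv":
            ref = cds[off]
            alt = rng.choice([b for b in "ACGT" if b != ref])
        elif kind == "inframe_ins":
            ref = ""
            alt = rng.choice(SENSE_CODONS)
        elif kind == "inframe_del":
            ref = cds[off : off + 3]
            alt = ""
        elif kind == "fs_del":
            width = rng.choice([1, 2])
            ref = cds[off : off + width]
            alt = ""
        else:
            ref = ""
            alt = "".join(rng.choices("ACGT", k=rng.choice([1, 2])))
        edits.append(cds_effect(model, off, ref, alt, genome))
    return edits


def oracle_mutant_protein(layout, effects, max_tail: int = 100) -> str:
    """Brute-force re-translation of the fully edited CDS."""
    cds = layout["cds"]
    ordered = sorted(effects, key=lambda e: e.cds_offset)
    edited = cds
    for e in sorted(ordered, key=lambda e: e.cds_offset, reverse=True):
        edited = edited[: e.cds_offset] + e.cds_alt + edited[e.cds_offset + len(e.cds_ref) :]
    shift = 0
    fs_off = None
    for e in ordered:
        if (len(e.cds_alt) - len(e.cds_ref)) % 3 != 0 and fs_off is None:
            fs_off = e.cds_offset + shift
        shift += len(e.cds_alt) - len(e.cds_ref)
    if fs_off is not None:
        edited += layout["downstream"]
    prot = str(Seq(edited[: len(edited) // 3 * 3]).translate()).split("*")[0]
    if fs_off is not None:
        prot = prot[: fs_off // 3 + max_tail]
    return prot


# ---------------------------------------------------------------------------
# RNA read construction for phasing tests
# ---------------------------------------------------------------------------

def make_reads(genome: dict[str, str], placements) -> list:
    """Aligned segments over a dict genome.

    ``placements`` is a list of (qname, chrom, start, {gpos: base}) tuples;
    reads are 40 bp perfect matches with the given substitutions.
    """
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in sorted(genome.items())],
    })
    ids = {name: i for i, name in enumerate(sorted(genome))}
    reads = []
    for qname, chrom, start, subs in placements:
        seq = list(genome[chrom][start : start + 40])
        for gpos, base in subs.items():
            seq[gpos - start] = base
        a = pysam.AlignedSegment(header)
        a.query_name = qname
        a.query_sequence = "".join(seq)
        a.flag = 0
        a.reference_id = ids[chrom]
        a.reference_start = start
        a.mapping_quality = 60
        a.cigarstring = "40M"
        reads.append(a)
    return reads


# ---------------------------------------------------------------------------
# literal re-execution of the boosting pseudocode
# ---------------------------------------------------------------------------

@dataclass
class OracleCandidate:
    iar_id: str
    best_rank: float
    features: dict[str, float]


def _tied_rank_scores(values: list[float]) -> list[float]:
    m = len(values)
    if m == 1:
        return [0.0]
    scores = []
    for x in values:
        less = sum(1 for v in values if v < x)
        equal = sum(1 for v in values if v == x)
        avg_rank = less + (equal + 1) / 2
        scores.append((avg_rank - 1) / (m - 1))
    return scores


def algo1_oracle(cands: list[OracleCandidate], weights: dict[str, float],
                 iterations: int = 3) -> list[str]:
    """Step-by-step hand simulation; returns the final id order."""
    order = sorted(cands, key=lambda c: (c.best_rank, -c.features["npa"], c.iar_id))
    names = list(weights)
    per_feature = {
        f: _tied_rank_scores([c.features[f] for c in order]) for f in names
    }
    boosts = {
        c.iar_id: sum(weights[f] * per_feature[f][i] for f in names)
        for i, c in enumerate(order)
    }
    for _ in range(iterations):
        scored = []
        for old_rank, c in enumerate(order, start=1):
            new_rank = old_rank * (1 - boosts[c.iar_id])
            scored.append((new_rank, c.best_rank, c.iar_id, c))
        scored.sort(key=lambda t: (t[0], t[1], t[2]))
        order = [c for _, _, _, c in scored]
    return [c.iar_id for c in order]
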