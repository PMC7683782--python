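"""Translate consensus variants and fusions into immunoactive regions.

An immunoactive region (IAR) is the contiguous mutant peptide context
around one or more nearby coding events. Events within 27/30/45 bp of each
other in spliced-CDS coordinates (for 9-, 10- and 15-mer peptides
respectively) are chained into one region; chained events are optionally
phased with RNA-seq reads to confirm they co-occur on one haplotype.
Fusion regions carry (n-1)*3 coding bases from each side of the junction,
translated in the 5' partner's frame and truncated at the first stop.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .consensus import ConsensusVariant
from .errors import ReferenceMismatchError, UnresolvableOverlapError
from .formats import FusionRecord
from .transcript import TranscriptModel, fetch, revcomp, translate_to_stop

log = logging.getLogger(__name__)

#: chaining window in spliced-CDS bp per peptide length (3n = n codons)
CHAIN_WINDOW = {9: 27, 10: 30, 15: 45}
PEPTIDE_LENGTHS = (9, 10, 15)

MITO_CHROMS = {"chrM", "MT", "chrMT", "M"}
LINC_BIOTYPES = {"lincRNA", "lncRNA"}


# ---------------------------------------------------------------------------
# coding-effect annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodingEffect:
    """The effect of one consensus variant on one coding transcript.

    ``cds_ref``/``cds_alt`` are the transcript-strand allele strings at
    ``cds_offset`` in the spliced CDS; they drive sequence editing.
    """

    variant: ConsensusVariant
    transcript_id: str
    cds_offset: int
    effect_class: str  # missense | synonymous | inframe_ins | inframe_del | frameshift | stop_gain | stop_loss
    ref_aa: str
    alt_aa_or_tail: str
    cds_ref: str
    cds_alt: str

    @property
    def protein_pos(self) -> int:
        return self.cds_offset // 3 + 1

    @property
    def key(self) -> tuple:
        return (self.transcript_id, self.cds_offset, self.cds_ref, self.cds_alt)


def _check_reference(variant: ConsensusVariant, genome) -> None:
    if variant.ref:
        seen = fetch(genome, variant.chrom, variant.pos, variant.end)
        if seen != variant.ref:
            raise ReferenceMismatchError(
                f"{variant.chrom}:{variant.vcf_pos}: genome has {seen!r}, "
                f"variant claims {variant.ref!r}"
            )


def _cds_edit(variant: ConsensusVariant, model: TranscriptModel) -> tuple[int, str, str] | None:
    """Map a trimmed variant onto spliced-CDS coordinates of one model.

    Returns (cds_offset, cds_ref, cds_alt) on the transcript strand, or
    None when the variant does not edit this model's CDS. Events spanning
    a splice boundary are skipped with a warning.
    """
    minus = model.strand == "-"
    if variant.kind == "snv":
        off = model.genomic_to_cds(variant.pos)
        if off is None:
            return None
        ref = revcomp(variant.ref) if minus else variant.ref
        alt = revcomp(variant.alt) if minus else variant.alt
        return off, ref, alt
    if variant.kind == "insertion":
        anchor = variant.pos - 1 if minus else variant.pos
        off = model.genomic_to_cds(anchor)
        if off is None:
            return None
        alt = revcomp(variant.alt) if minus else variant.alt
        return off, "", alt
    # deletion
    span = range(variant.pos, variant.end)
    offsets = [model.genomic_to_cds(g) for g in span]
    if all(o is None for o in offsets):
        return None
    if any(o is None for o in offsets):
        log.warning("deletion at %s:%d spans a CDS boundary in %s; skipped",
                    variant.chrom, variant.vcf_pos, model.transcript_id)
        return None
    start = min(offsets)
    if sorted(offsets) != list(range(start, start + len(offsets))):
        log.warning("deletion at %s:%d spans a splice junction in %s; skipped",
                    variant.chrom, variant.vcf_pos, model.transcript_id)
        return None
    ref = revcomp(variant.ref) if minus else variant.ref
    return start, ref, ""


def annotate_coding_effects(
    variant: ConsensusVariant,
    models: list[TranscriptModel],
    genome,
) -> list[CodingEffect]:
    """One effect per coding transcript whose CDS the variant edits.

    Raises :class:`ReferenceMismatchError` when the genome disagrees with
    the variant's REF allele.
    """
    _check_reference(variant, genome)
    effects: list[CodingEffect] = []
    for model in models:
        if not model.is_coding or model.chrom != variant.chrom:
            continue
        edit = _cds_edit(variant, model)
        if edit is None:
            continue
        off, cref, calt = edit
        cds = model.spliced_cds(genome)
        if cref and cds[off : off + len(cref)] != cref:
            raise ReferenceMismatchError(
                f"{variant.chrom}:{variant.vcf_pos}: spliced CDS of "
                f"{model.transcript_id} has {cds[off:off + len(cref)]!r}, expected {cref!r}"
            )
        shift = len(calt) - len(cref)
        if variant.kind == "snv":
            codon_i = off // 3
            codon = cds[codon_i * 3 : codon_i * 3 + 3]
            mut = codon[: off % 3] + calt + codon[off % 3 + 1 :]
            ref_aa = translate_to_stop(codon) or "*"
            alt_aa = translate_to_stop(mut) or "*"
            if alt_aa == "*" and ref_aa != "*":
                cls = "stop_gain"
            elif ref_aa == "*" and alt_aa != "*":
                cls = "stop_loss"
            elif ref_aa == alt_aa:
                cls = "synonymous"
            else:
                cls = "missense"
            effects.append(CodingEffect(variant, model.transcript_id, off, cls,
                                        ref_aa, alt_aa, cref, calt))
        else:
            if shift % 3 == 0:
                cls = "inframe_ins" if shift > 0 else "inframe_del"
            else:
                cls = "frameshift"
            ref_aa = translate_to_stop(cds[(off // 3) * 3 : (off // 3) * 3 + 3]) or "*"
            tail = translate_to_stop(calt) if cls == "inframe_ins" else ""
            effects.append(CodingEffect(variant, model.transcript_id, off, cls,
                                        ref_aa, tail, cref, calt))
    return effects


def filter_expressed(
    effects: list[CodingEffect],
    expression: pd.DataFrame | None,
    min_tpm: float = 0.0,
) -> list[CodingEffect]:
    """Keep effects whose harboring isoform has TPM strictly above min_tpm.

    A transcript absent from the expression table counts as TPM 0; with no
    table at all the filter is a no-op.
    """
    from .formats import expression_lookup

    if expression is None:
        return list(effects)
    tpm = expression_lookup(expression)
    return [e for e in effects if tpm(e.transcript_id) > min_tpm]


# ---------------------------------------------------------------------------
# mutant-protein construction
# ---------------------------------------------------------------------------

@dataclass
class MutantProtein:
    """Edited protein with per-residue provenance.

    ``mutant_indices`` are 0-based residue indices whose codons were
    touched by an edit; for a frameshift every residue from
    ``frameshift_start`` onward is mutant.
    """

    seq: str
    wt_seq: str
    mutant_indices: frozenset[int]
    frameshift_start: int | None = None


def mutant_protein(
    model: TranscriptModel,
    effects: list[CodingEffect],
    genome,
    max_tail: int = 100,
) -> MutantProtein:
    """Apply non-overlapping CDS edits and re-translate.

    SNVs and in-frame indels are injected in place; the first frameshift
    switches to novel translation that continues past the annotated stop
    (into the 3' UTR and beyond if needed) until a stop codon or
    ``max_tail`` novel residues.
    """
    cds = model.spliced_cds(genome)
    wt = translate_to_stop(cds)
    ordered = sorted(effects, key=lambda e: (e.cds_offset, e.key))
    for a, b in zip(ordered, ordered[1:]):
        if a.cds_offset + len(a.cds_ref) > b.cds_offset:
            raise UnresolvableOverlapError(
                f"effects at CDS offsets {a.cds_offset} and {b.cds_offset} "
                f"overlap on {model.transcript_id}"
            )
    pieces: list[str] = []
    cursor = 0
    shift = 0
    spans: list[tuple[int, int]] = []  # edited-coordinate spans of the edits
    fs_at: int | None = None
    for e in ordered:
        pieces.append(cds[cursor : e.cds_offset])
        start = e.cds_offset + shift
        pieces.append(e.cds_alt)
        spans.append((start, start + max(len(e.cds_alt), 1)))
        if (len(e.cds_alt) - len(e.cds_ref)) % 3 != 0 and fs_at is None:
            fs_at = start
        shift += len(e.cds_alt) - len(e.cds_ref)
        cursor = e.cds_offset + len(e.cds_ref)
    pieces.append(cds[cursor:])
    edited = "".join(pieces)

    if fs_at is not None:
        edited += model.downstream_of_cds(genome, 3 * (max_tail + 2))
    seq = translate_to_stop(edited)
    if fs_at is not None:
        fs_res = fs_at // 3
        seq = seq[: fs_res + max_tail]
        mutant = frozenset(range(fs_res, len(seq)))
        return MutantProtein(seq, wt, mutant, frameshift_start=fs_res)

    mutant: set[int] = set()
    for s, e in spans:
        first = s // 3
        last = (max(e, s + 1) - 1) // 3
        mutant.update(i for i in range(first, last + 1) if i < len(seq))
    return MutantProtein(seq, wt, frozenset(mutant))


# ---------------------------------------------------------------------------
# chaining and phasing
# ---------------------------------------------------------------------------

def chain_events(effects: list[CodingEffect], n: int) -> list[list[CodingEffect]]:
    """Single-linkage grouping of events within the n-mer chaining window."""
    window = CHAIN_WINDOW[n]
    ordered = sorted(effects, key=lambda e: (e.cds_offset, e.key))
    groups: list[list[CodingEffect]] = []
    for e in ordered:
        if groups and e.cds_offset - groups[-1][-1].cds_offset <= window:
            groups[-1].append(e)
        else:
            groups.append([e])
    return groups


@dataclass(frozen=True)
class PhasingEvidence:
    """RNA read counts for one adjacent event pair."""

    cis_reads: int = 0
    trans_reads: int = 0
    uninformative: int = 0


def _read_base(read, gpos: int) -> str | None:
    seq = read.query_sequence
    if seq is None:
        return None
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos == gpos:
            return seq[qpos].upper()
    return None


def pair_evidence(e1: CodingEffect, e2: CodingEffect, reads) -> PhasingEvidence:
    """Count cis/trans RNA reads over two SNV events.

    Pairs involving indels are uninformative with this base-level check.
    """
    v1, v2 = e1.variant, e2.variant
    if v1.kind != "snv" or v2.kind != "snv":
        return PhasingEvidence()
    cis = trans = noninf = 0
    skipped = 0
    for read in reads:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            skipped += 1
            continue
        if read.reference_name != v1.chrom:
            continue
        b1 = _read_base(read, v1.pos)
        b2 = _read_base(read, v2.pos)
        if b1 is None or b2 is None:
            noninf += 1
            continue
        a1, a2 = b1 == v1.alt, b2 == v2.alt
        r1, r2 = b1 == v1.ref, b2 == v2.ref
        if a1 and a2:
            cis += 1
        elif (a1 and r2) or (r1 and a2):
            trans += 1
        else:
            noninf += 1
    if skipped:
        log.debug("phasing: ignored %d unaligned/secondary records", skipped)
    return PhasingEvidence(cis, trans, noninf)


def phase_group(
    group: list[CodingEffect],
    rna_reads,
    min_cis: int = 1,
    evidence_cache: dict | None = None,
) -> list[tuple[list[CodingEffect], str]]:
    """Split a chained group wherever RNA evidence does not support cis.

    An adjacent pair stays joined iff cis_reads >= min_cis and
    cis_reads >= trans_reads; otherwise the group splits there. Groups of
    one event are ``not_applicable``; split products without joined
    evidence are ``no_evidence``.
    """
    if len(group) == 1:
        return [(list(group), "not_applicable")]
    reads = list(rna_reads)
    ordered = sorted(group, key=lambda e: (e.cds_offset, e.key))
    sub: list[CodingEffect] = [ordered[0]]
    out: list[list[CodingEffect]] = []
    for prev, cur in zip(ordered, ordered[1:]):
        cache_key = (prev.key, cur.key)
        if evidence_cache is not None and cache_key in evidence_cache:
            ev = evidence_cache[cache_key]
        else:
            ev = pair_evidence(prev, cur, reads)
            if evidence_cache is not None:
                evidence_cache[cache_key] = ev
        if ev.cis_reads >= min_cis and ev.cis_reads >= ev.trans_reads:
            sub.append(cur)
        else:
            out.append(sub)
            sub = [cur]
    out.append(sub)
    return [(g, "cis_confirmed" if len(g) > 1 else "no_evidence") for g in out]


# ---------------------------------------------------------------------------
# immunoactive regions
# ---------------------------------------------------------------------------

@dataclass
class ImmunoActiveRegion:
    """Mutant (and wildtype) peptide context for one event group."""

    iar_id: str
    source_type: str  # snv | indel | fusion
    gene_name: str
    chrom: str
    transcript_ids: list[str]
    events: list = field(default_factory=list)
    peptides: dict[int, tuple[str, str | None]] = field(default_factory=dict)
    mutant_positions: dict[int, tuple[int, ...]] = field(default_factory=dict)
    tpm: float = 0.0
    phased: str = "not_applicable"

    def mutant_peptide(self, n: int) -> str | None:
        pair = self.peptides.get(n)
        return pair[0] if pair else None

    def wildtype_peptide(self, n: int) -> str | None:
        pair = self.peptides.get(n)
        return pair[1] if pair else None


def peptide_window(
    mp: MutantProtein, n: int
) -> tuple[str, str | None, tuple[int, ...]] | None:
    """Cut the n-mer-bearing window around the mutant residues.

    The window runs (n-1) residues upstream of the first mutant residue
    through (n-1) residues past the last, clipped at the protein ends.
    The wildtype counterpart is the same coordinates in the unedited
    protein, absent for frameshift products.
    """
    idx = sorted(mp.mutant_indices)
    if not idx:
        return None
    start = max(0, idx[0] - (n - 1))
    end = min(len(mp.seq), idx[-1] + n)
    mut = mp.seq[start:end]
    if not mut:
        return None
    if mp.frameshift_start is not None:
        wt = None
        positions = tuple(i - start for i in idx if start <= i < end)
    else:
        wt = mp.wt_seq[start:end]
        if wt == mut:
            return None
        positions = tuple(i for i in range(len(mut)) if i >= len(wt) or mut[i] != wt[i])
    return mut, wt, positions


def build_snv_iar(
    group: list[CodingEffect],
    model: TranscriptModel,
    mp: MutantProtein,
    n: int,
) -> tuple[str, str | None, tuple[int, ...]] | None:
    """Window for one chained, phased event group (None when silent)."""
    if all(e.effect_class == "synonymous" for e in group):
        return None
    return peptide_window(mp, n)


# ---------------------------------------------------------------------------
# fusion handling
# ---------------------------------------------------------------------------

@dataclass
class FusionFilterOptions:
    filter_mito: bool = True
    filter_ig: bool = True
    filter_readthrough: bool = True
    filter_linc: bool = True
    rt_threshold: int = 500_000


def _gene_index(models: list[TranscriptModel]) -> dict[str, list[TranscriptModel]]:
    index: dict[str, list[TranscriptModel]] = {}
    for m in models:
        index.setdefault(m.gene_name, []).append(m)
        index.setdefault(m.gene_id, []).append(m)
    return index


def filter_fusions(
    fusions: list[FusionRecord],
    models: list[TranscriptModel],
    options: FusionFilterOptions | None = None,
) -> tuple[list[FusionRecord], list[tuple[FusionRecord, list[str]]]]:
    """Apply the four independent fusion filters.

    Reason codes: ``mito_mito`` (both partners on the mitochondrial
    contig), ``ig_ig`` (both immunoglobulin biotypes), ``readthrough``
    (same chromosome, breakpoints within the readthrough distance),
    ``linc_5p`` (non-coding lincRNA 5' partner), ``unresolved_gene``.
    A fusion may accumulate several reasons but is emitted once.
    """
    options = options or FusionFilterOptions()
    index = _gene_index(models)
    kept: list[FusionRecord] = []
    rejected: list[tuple[FusionRecord, list[str]]] = []
    for fus in fusions:
        reasons: list[str] = []
        m5 = index.get(fus.gene5)
        m3 = index.get(fus.gene3)
        if not m5 or not m3:
            rejected.append((fus, ["unresolved_gene"]))
            continue
        chrom5, chrom3 = m5[0].chrom, m3[0].chrom
        bio5, bio3 = m5[0].biotype, m3[0].biotype
        if options.filter_mito and chrom5 in MITO_CHROMS and chrom3 in MITO_CHROMS:
            reasons.append("mito_mito")
        if options.filter_ig and bio5.startswith("IG_") and bio3.startswith("IG_"):
            reasons.append("ig_ig")
        if (
            options.filter_readthrough
            and fus.chrom5 == fus.chrom3
            and abs(fus.breakpoint5 - fus.breakpoint3) <= options.rt_threshold
        ):
            reasons.append("readthrough")
        if options.filter_linc and bio5 in LINC_BIOTYPES:
            reasons.append("linc_5p")
        if reasons:
            rejected.append((fus, reasons))
        else:
            kept.append(fus)
    return kept, rejected


@dataclass
class FusionBuild:
    """Outcome of translating one fusion junction at one peptide length."""

    ok: bool
    reason: str = ""
    peptide: str = ""
    positions: tuple[int, ...] = ()
    transcript5: str | None = None
    transcript3: str | None = None


def build_fusion_iar(
    fusion: FusionRecord,
    models: list[TranscriptModel],
    genome,
    n: int,
) -> FusionBuild:
    """Translate (n-1)*3 bp from each side of the junction in the 5' frame.

    No region is produced when the 5' breakpoint has no preceding codons
    (UTR or non-coding 5' partner); an intronic 5' breakpoint is an
    explicit unsupported case.
    """
    flank = (n - 1) * 3
    if fusion.junction_seq5 and fusion.junction_seq3:
        up_all = fusion.junction_seq5
        s = max(0, len(up_all) - flank)
        s -= s % 3  # junction sequence is assumed to start in frame
        up = up_all[s:]
        down = fusion.junction_seq3[:flank]
        t5 = t3 = None
    else:
        index = _gene_index(models)
        m5 = index.get(fusion.gene5, [])
        m3 = index.get(fusion.gene3, [])
        if not m5 or not m3:
            return FusionBuild(False, "unresolved_gene")
        bp5, bp3 = fusion.breakpoint5, fusion.breakpoint3
        coding5 = [m for m in m5 if m.is_coding and m.genomic_to_cds(bp5) is not None]
        if not coding5:
            if any(m.contains_intronic(bp5) for m in m5):
                return FusionBuild(False, "intronic_5p")
            return FusionBuild(False, "utr_5p")
        t5 = sorted(coding5, key=lambda m: m.transcript_id)[0]
        off5 = t5.genomic_to_cds(bp5)
        length = off5 + 1
        s = max(0, length - flank)
        s -= s % 3
        up = t5.spliced_cds(genome)[s:length]
        exonic3 = [m for m in m3 if m.contains_exonic(bp3)]
        if exonic3:
            t3 = sorted(exonic3, key=lambda m: m.transcript_id)[0]
            down = t3.exonic_from(genome, bp3, flank)
        else:
            t3 = None
            if fusion.strand3 == "+":
                down = fetch(genome, fusion.chrom3, bp3, bp3 + flank)
            else:
                down = revcomp(fetch(genome, fusion.chrom3, bp3 - flank + 1, bp3 + 1))
    if not up:
        return FusionBuild(False, "utr_5p")
    peptide = translate_to_stop(up + down)
    junction_res = len(up) // 3
    if len(peptide) <= junction_res:
        return FusionBuild(False, "stop_before_junction")
    positions = tuple(range(junction_res, len(peptide)))
    return FusionBuild(
        True, peptide=peptide, positions=positions,
        transcript5=t5.transcript_id if t5 else None,
        transcript3=t3.transcript_id if t3 else None,
    )


# ---------------------------------------------------------------------------
# sample-level orchestration
# ---------------------------------------------------------------------------

@dataclass
class TranslationOptions:
    min_tpm: float = 0.0
    max_tail: int = 100
    min_cis: int = 1
    fusion_filters: FusionFilterOptions = field(default_factory=FusionFilterOptions)


@dataclass
class TranslationResult:
    iars: list[ImmunoActiveRegion]
    fusion_rejections: list[tuple[FusionRecord, list[str]]]
    phase_records: list[tuple[str, int, int, bool]]  # chrom, vcf_pos1, vcf_pos2, joined


def _draft_key(events: list[CodingEffect]) -> tuple:
    return tuple(sorted(e.key for e in events))


def translate_sample(
    variants: list[ConsensusVariant],
    fusions: list[FusionRecord],
    models: list[TranscriptModel],
    genome,
    expression: pd.DataFrame | None = None,
    rna_reads=None,
    options: TranslationOptions | None = None,
) -> TranslationResult:
    """Run the full variant/fusion-to-IAR translation for one sample."""
    from .formats import expression_lookup

    options = options or TranslationOptions()
    tpm_of = expression_lookup(expression)
    by_tid = {m.transcript_id: m for m in models}

    # annotate and bucket effects per transcript
    effects_by_tid: dict[str, list[CodingEffect]] = {}
    for variant in variants:
        effects = annotate_coding_effects(variant, models, genome)
        effects = filter_expressed(effects, expression, options.min_tpm)
        for e in effects:
            if e.effect_class == "synonymous":
                continue
            effects_by_tid.setdefault(e.transcript_id, []).append(e)

    reads = list(rna_reads) if rna_reads is not None else None
    evidence_cache: dict = {}
    phase_records: list[tuple[str, int, int, bool]] = []
    phase_seen: set[tuple] = set()

    # drafts keyed by (transcript_id, event-set): n -> window
    drafts: dict[tuple, dict] = {}
    for tid in sorted(effects_by_tid):
        model = by_tid[tid]
        effects = effects_by_tid[tid]
        for n in PEPTIDE_LENGTHS:
            for group in chain_events(effects, n):
                if reads is not None:
                    phased_groups = phase_group(group, reads, options.min_cis, evidence_cache)
                    ordered = sorted(group, key=lambda e: (e.cds_offset, e.key))
                    joined_pairs = {
                        (a.key, b.key)
                        for sub, _ in phased_groups
                        for a, b in zip(sub, sub[1:])
                    }
                    for a, b in zip(ordered, ordered[1:]):
                        rec_key = (a.variant.key, b.variant.key)
                        if rec_key not in phase_seen:
                            phase_seen.add(rec_key)
                            phase_records.append((
                                a.variant.chrom, a.variant.vcf_pos, b.variant.vcf_pos,
                                (a.key, b.key) in joined_pairs,
                            ))
                else:
                    status = "not_applicable" if len(group) == 1 else "no_evidence"
                    phased_groups = [(group, status)]
                for sub, status in phased_groups:
                    mp = mutant_protein(model, sub, genome, options.max_tail)
                    window = build_snv_iar(sub, model, mp, n)
                    if window is None:
                        continue
                    key = (tid, _draft_key(sub))
                    entry = drafts.setdefault(key, {
                        "model": model, "events": sub, "phased": status, "windows": {},
                    })
                    entry["windows"][n] = window

    # assemble per-transcript drafts, then deduplicate identical contexts
    assembled: dict[tuple, ImmunoActiveRegion] = {}
    for (tid, _ekey), entry in sorted(drafts.items()):
        model: TranscriptModel = entry["model"]
        events = entry["events"]
        kinds = {e.variant.kind for e in events}
        source = "indel" if kinds & {"insertion", "deletion"} else "snv"
        peptides = {n: (w[0], w[1]) for n, w in entry["windows"].items()}
        positions = {n: w[2] for n, w in entry["windows"].items()}
        context_key = (source, tuple(sorted(peptides.items())))
        if context_key in assembled:
            iar = assembled[context_key]
            if tid not in iar.transcript_ids:
                iar.transcript_ids.append(tid)
                iar.tpm += tpm_of(tid)
        else:
            assembled[context_key] = ImmunoActiveRegion(
                iar_id="", source_type=source, gene_name=model.gene_name,
                chrom=model.chrom, transcript_ids=[tid], events=list(events),
                peptides=peptides, mutant_positions=positions,
                tpm=tpm_of(tid), phased=entry["phased"],
            )
    iars = list(assembled.values())

    # fusions
    kept, rejections = filter_fusions(fusions, models, options.fusion_filters)
    for fus in kept:
        windows: dict[int, FusionBuild] = {}
        fail_reason = None
        for n in PEPTIDE_LENGTHS:
            build = build_fusion_iar(fus, models, genome, n)
            if build.ok:
                windows[n] = build
            else:
                fail_reason = build.reason
        if not windows:
            rejections.append((fus, [fail_reason or "untranslatable"]))
            continue
        any_build = next(iter(windows.values()))
        tids = [t for t in (any_build.transcript5, any_build.transcript3) if t]
        iars.append(ImmunoActiveRegion(
            iar_id="", source_type="fusion", gene_name=fus.name,
            chrom=fus.chrom5, transcript_ids=tids, events=[fus],
            peptides={n: (b.peptide, None) for n, b in windows.items()},
            mutant_positions={n: b.positions for n, b in windows.items()},
            tpm=sum(tpm_of(t) for t in tids), phased="not_applicable",
        ))

    iars.sort(key=lambda r: (r.chrom, r.gene_name, r.source_type,
                             r.mutant_peptide(9) or r.mutant_peptide(10) or r.mutant_peptide(15) or ""))
    for i, iar in enumerate(iars, 1):
        iar.iar_id = f"iar_{i:04d}_{iar.gene_name.replace('--', '_')}"
    return TranslationResult(iars, rejections, phase_records)


# ---------------------------------------------------------------------------
# stage-file serialization
# ---------------------------------------------------------------------------

IAR_TABLE_COLUMNS = [
    "iar_id", "source_type", "gene_name", "chrom", "transcript_ids", "tpm", "phased",
    "mut_9", "wt_9", "pos_9", "mut_10", "wt_10", "pos_10", "mut_15", "wt_15", "pos_15",
]


def write_iar_table(iars: list[ImmunoActiveRegion], path) -> None:
    rows = []
    for iar in iars:
        row = {
            "iar_id": iar.iar_id, "source_type": iar.source_type,
            "gene_name": iar.gene_name, "chrom": iar.chrom,
            "transcript_ids": ",".join(iar.transcript_ids),
            "tpm": repr(iar.tpm), "phased": iar.phased,
        }
        for n in PEPTIDE_LENGTHS:
            mut = iar.mutant_peptide(n)
            row[f"mut_{n}"] = mut or ""
            row[f"wt_{n}"] = iar.wildtype_peptide(n) or ""
            row[f"pos_{n}"] = ",".join(map(str, iar.mutant_positions.get(n, ())))
        rows.append(row)
    pd.DataFrame(rows, columns=IAR_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_iar_table(path) -> list[ImmunoActiveRegion]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    iars = []
    for _, row in df.iterrows():
        peptides: dict[int, tuple[str, str | None]] = {}
        positions: dict[int, tuple[int, ...]] = {}
        for n in PEPTIDE_LENGTHS:
            if row[f"mut_{n}"]:
                peptides[n] = (row[f"mut_{n}"], row[f"wt_{n}"] or None)
                pos = row[f"pos_{n}"]
                positions[n] = tuple(int(x) for x in pos.split(",")) if pos else ()
        iars.append(ImmunoActiveRegion(
            iar_id=row["iar_id"], source_type=row["source_type"],
            gene_name=row["gene_name"], chrom=row["chrom"],
            transcript_ids=row["transcript_ids"].split(",") if row["transcript_ids"] else [],
            peptides=peptides, mutant_positions=positions,
            tpm=float(row["tpm"]), phased=row["phased"],
        ))
    return iars


def write_fusion_rejections(rejections, path) -> None:
    rows = [{"fusion": fus.key, "reasons": ",".join(reasons)} for fus, reasons in rejections]
    pd.DataFrame(rows, columns=["fusion", "reasons"]).to_csv(path, sep="\t", index=False)
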