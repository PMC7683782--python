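"""End-to-end per-patient orchestration with stage-boundary resumability.

Stages run in order consensus -> translation -> binding -> ranking; each
stage writes its result as a TSV in the output directory and is skipped
on re-runs when its output is newer than all of its inputs. A manifest
records the package version, seed and options so a run can be reproduced
byte-identically elsewhere.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pysam
import yaml

from . import __version__
from . import binding, consensus, formats, rankboost, transgene
from .errors import ConfigurationError
from .transcript import open_genome

log = logging.getLogger(__name__)

HLA_SOURCES = ("tumor_dna", "normal_dna", "tumor_rna")


@dataclass
class RunOptions:
    min_support: int = 2
    require_pass: bool = True
    min_tpm: float = 0.0
    max_tail: int = 100
    min_cis: int = 1
    rt_threshold: int = 500_000
    filter_mito: bool = True
    filter_ig: bool = True
    filter_readthrough: bool = True
    filter_linc: bool = True
    accept_threshold: float = 5.0
    iterations: int = 3
    seed: int = 17
    predictor: str = "mock"
    motifs: list[str] = field(default_factory=list)
    weights_i: dict[str, float] | None = None
    weights_ii: dict[str, float] | None = None

    def boost_weights(self, mhc_class: str) -> rankboost.BoostWeights:
        override = self.weights_i if mhc_class == "I" else self.weights_ii
        if override is None:
            return (rankboost.BoostWeights.mhc_i_defaults() if mhc_class == "I"
                    else rankboost.BoostWeights.mhc_ii_defaults())
        unknown = set(override) - set(rankboost.FEATURE_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown boost features: {sorted(unknown)}")
        return rankboost.BoostWeights(**{f"w_{k}": v for k, v in override.items()})


@dataclass
class RunConfig:
    vcfs: dict[str, Path]
    indel_vcf: Path | None
    gtf: Path
    fasta: Path
    expression: Path
    hla: dict[str, Path]
    bedpe: Path | None = None
    rna_sam: Path | None = None
    outdir: Path = Path("neopept_out")
    options: RunOptions = field(default_factory=RunOptions)

    def validate(self) -> None:
        required = list(self.vcfs.values()) + [self.gtf, self.fasta, self.expression]
        required += list(self.hla.values())
        for p in [self.indel_vcf, self.bedpe, self.rna_sam]:
            if p is not None:
                required.append(p)
        for p in required:
            if not Path(p).exists():
                raise ConfigurationError(f"input path does not exist: {p}")
        if not self.vcfs:
            raise ConfigurationError("at least one SNV caller VCF is required")
        if not 0 < self.options.accept_threshold <= 100:
            raise ConfigurationError("accept_threshold must be in (0, 100]")
        if self.options.iterations < 0:
            raise ConfigurationError("iterations must be >= 0")
        # weight validation happens on construction
        self.options.boost_weights("I")
        self.options.boost_weights("II")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = Path(path).parent

    def _p(value):
        if value is None:
            return None
        p = Path(value)
        return p if p.is_absolute() else base / p

    opts = RunOptions(**(raw.get("options") or {}))
    config = RunConfig(
        vcfs={c: _p(p) for c, p in (raw.get("vcfs") or {}).items()},
        indel_vcf=_p(raw.get("indel_vcf")),
        bedpe=_p(raw.get("bedpe")),
        gtf=_p(raw["gtf"]),
        fasta=_p(raw["fasta"]),
        expression=_p(raw["expression"]),
        hla={s: _p(p) for s, p in (raw.get("hla") or {}).items()},
        rna_sam=_p(raw.get("rna_sam")),
        outdir=_p(raw.get("outdir") or "neopept_out"),
        options=opts,
    )
    config.validate()
    return config


def dump_config(config: RunConfig, path) -> None:
    raw = {
        "vcfs": {c: str(p) for c, p in config.vcfs.items()},
        "indel_vcf": str(config.indel_vcf) if config.indel_vcf else None,
        "bedpe": str(config.bedpe) if config.bedpe else None,
        "gtf": str(config.gtf),
        "fasta": str(config.fasta),
        "expression": str(config.expression),
        "hla": {s: str(p) for s, p in config.hla.items()},
        "rna_sam": str(config.rna_sam) if config.rna_sam else None,
        "outdir": str(config.outdir),
        "options": dataclasses.asdict(config.options),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)


def config_for_fixture(fixture, outdir=None, seed: int = 17) -> RunConfig:
    """Build a run configuration pointing at a generated fixture set."""
    from .fixtures import CALLERS, DEFAULT_MOTIFS

    paths = fixture.paths
    return RunConfig(
        vcfs={c: paths[f"vcf_{c}"] for c in CALLERS},
        indel_vcf=paths["indel_vcf"],
        bedpe=paths["bedpe"],
        gtf=paths["gtf"],
        fasta=paths["fasta"],
        expression=paths["expression"],
        hla={s: paths[f"hla_{s}"] for s in HLA_SOURCES},
        rna_sam=paths["rna_sam"],
        outdir=Path(outdir) if outdir else fixture.outdir / "out",
        options=RunOptions(seed=seed, motifs=list(DEFAULT_MOTIFS)),
    )


@dataclass
class PipelineResult:
    consensus_variants: list
    haplotype: consensus.ConsensusHaplotype
    iars: list
    fusion_rejections: list[tuple[str, list[str]]]
    phase_records: list[tuple[str, int, int, bool]]
    calls: dict[str, list]
    ranked: dict[str, list]


def _fresh(output: Path, inputs: list[Path]) -> bool:
    if not output.exists():
        return False
    out_mtime = output.stat().st_mtime
    return all(Path(p).stat().st_mtime <= out_mtime for p in inputs if p is not None)


def _write_phase_records(records, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos1\tpos2\tjoined\n")
        for chrom, p1, p2, joined in records:
            fh.write(f"{chrom}\t{p1}\t{p2}\t{int(joined)}\n")


def _read_phase_records(path: Path) -> list[tuple[str, int, int, bool]]:
    records = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            chrom, p1, p2, joined = line.rstrip("\n").split("\t")
            records.append((chrom, int(p1), int(p2), bool(int(joined))))
    return records


def _read_fusion_rejections(path: Path) -> list[tuple[str, list[str]]]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    return [(row["fusion"], row["reasons"].split(",")) for _, row in df.iterrows()]


def make_predictor(options: RunOptions):
    if options.predictor == "mock":
        return binding.mock_predictor(seed=options.seed, motifs=tuple(options.motifs))
    raise ConfigurationError(f"unknown predictor {options.predictor!r}")


def run_pipeline(config: RunConfig, resume: bool = True) -> PipelineResult:
    config.validate()
    opts = config.options
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # -- stage 1: consensus ---------------------------------------------------
    cons_path = out / "consensus_variants.tsv"
    hla_path = out / "consensus_hla.txt"
    vcf_inputs = list(config.vcfs.values()) + ([config.indel_vcf] if config.indel_vcf else [])
    if resume and _fresh(cons_path, vcf_inputs) and _fresh(hla_path, list(config.hla.values())):
        log.info("consensus stage: reusing %s", cons_path)
        variants = consensus.read_consensus_variants(cons_path)
        haplotype = consensus.read_haplotype(hla_path)
    else:
        calls = {c: formats.read_vcf(p, c) for c, p in config.vcfs.items()}
        variants = consensus.merge_snv_calls(calls, opts.min_support, opts.require_pass)
        if config.indel_vcf:
            indel_calls = formats.read_vcf(config.indel_vcf, consensus.INDEL_SOURCE)
            variants = sorted(
                variants + consensus.extract_indels(indel_calls, opts.require_pass),
                key=lambda v: (v.chrom, v.pos, v.alt),
            )
        sources = [
            formats.read_haplotype_list(config.hla[s], s)
            if s in config.hla else formats.HaplotypeCallSet(s)
            for s in HLA_SOURCES
        ]
        haplotype = consensus.consensus_haplotype(sources)
        consensus.write_consensus_variants(variants, cons_path)
        consensus.write_haplotype(haplotype, hla_path)

    # -- stage 2: translation -------------------------------------------------
    iars_path = out / "iars.tsv"
    rej_path = out / "fusion_rejections.tsv"
    phase_path = out / "phase_records.tsv"
    stage2_inputs = [cons_path, config.gtf, config.fasta, config.expression,
                     config.bedpe, config.rna_sam]
    if resume and all(_fresh(p, stage2_inputs) for p in (iars_path, rej_path, phase_path)):
        log.info("translation stage: reusing %s", iars_path)
        iars = transgene.read_iar_table(iars_path)
        rejections = _read_fusion_rejections(rej_path)
        phase_records = _read_phase_records(phase_path)
    else:
        models = formats.read_gtf(config.gtf)
        genome = open_genome(config.fasta)
        expression = formats.read_expression(config.expression)
        fusions = formats.read_bedpe(config.bedpe) if config.bedpe else []
        rna_reads = None
        if config.rna_sam:
            with pysam.AlignmentFile(str(config.rna_sam), "r") as sam:
                rna_reads = list(sam)
        tr_options = transgene.TranslationOptions(
            min_tpm=opts.min_tpm, max_tail=opts.max_tail, min_cis=opts.min_cis,
            fusion_filters=transgene.FusionFilterOptions(
                filter_mito=opts.filter_mito, filter_ig=opts.filter_ig,
                filter_readthrough=opts.filter_readthrough,
                filter_linc=opts.filter_linc, rt_threshold=opts.rt_threshold,
            ),
        )
        result = transgene.translate_sample(
            variants, fusions, models, genome, expression, rna_reads, tr_options)
        iars = result.iars
        rejections = [(fus.key, reasons) for fus, reasons in result.fusion_rejections]
        phase_records = result.phase_records
        transgene.write_iar_table(iars, iars_path)
        import pandas as pd

        pd.DataFrame(
            [{"fusion": k, "reasons": ",".join(r)} for k, r in rejections],
            columns=["fusion", "reasons"],
        ).to_csv(rej_path, sep="\t", index=False)
        _write_phase_records(phase_records, phase_path)

    # -- stage 3: binding -----------------------------------------------------
    calls_paths = {c: out / f"epitope_calls_{c}.tsv" for c in ("I", "II")}
    if resume and all(_fresh(p, [iars_path, hla_path]) for p in calls_paths.values()):
        log.info("binding stage: reusing epitope tables")
        calls = {c: formats.read_epitope_table(p) for c, p in calls_paths.items()}
    else:
        predictor = make_predictor(opts)
        calls = binding.assay_iars(
            iars,
            class_i_alleles=haplotype.class_alleles("I"),
            class_ii_names=binding.class_ii_alleles(haplotype),
            predictor=predictor,
            accept_threshold=opts.accept_threshold,
        )
        for c, p in calls_paths.items():
            formats.write_epitope_table(calls[c], p)

    # -- stage 4: ranking -----------------------------------------------------
    ranked_paths = {c: out / f"ranked_{c}.tsv" for c in ("I", "II")}
    ranked: dict[str, list] = {}
    for mhc_class in ("I", "II"):
        rp = ranked_paths[mhc_class]
        if resume and _fresh(rp, [iars_path, calls_paths[mhc_class]]):
            ranked[mhc_class] = formats.read_iar_report(rp)
            continue
        by_iar: dict[str, list] = {}
        for call in calls[mhc_class]:
            by_iar.setdefault(call.iar_id, []).append(call)
        candidates = rankboost.make_candidates(iars, by_iar, mhc_class)
        ranked[mhc_class] = rankboost.boost_ranks(
            candidates, opts.boost_weights(mhc_class), opts.iterations)
        formats.write_iar_report(ranked[mhc_class], rp)

    manifest = {
        "package": "neopept",
        "version": __version__,
        "seed": opts.seed,
        "options": dataclasses.asdict(opts),
        "inputs": {
            "vcfs": {c: str(p) for c, p in config.vcfs.items()},
            "indel_vcf": str(config.indel_vcf) if config.indel_vcf else None,
            "bedpe": str(config.bedpe) if config.bedpe else None,
            "gtf": str(config.gtf), "fasta": str(config.fasta),
            "expression": str(config.expression),
            "hla": {s: str(p) for s, p in config.hla.items()},
            "rna_sam": str(config.rna_sam) if config.rna_sam else None,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        consensus_variants=variants, haplotype=haplotype, iars=iars,
        fusion_rejections=rejections, phase_records=phase_records,
        calls=calls, ranked=ranked,
    )
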