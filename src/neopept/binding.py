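"""Peptide:MHC binding-call generation and filtering.

Mutant k-mers are enumerated from each immunoactive region, scored by a
pluggable percentile-rank predictor (lower percentile = stronger predicted
binding against a background peptide set), filtered to the top 5% of
binders, and — only then — paired with a prediction for the wildtype
counterpart peptide so mutant-specific binding can be judged.
"""
from __future__ import annotations

import hashlib
import logging
import statistics
from dataclasses import dataclass
from typing import Protocol

from .errors import RecordError
from .formats import CLASS_I_LOCI, parse_hla_allele

log = logging.getLogger(__name__)

#: peptide length -> MHC class routing
CLASS_OF_LENGTH = {9: "I", 10: "I", 15: "II"}


@dataclass(frozen=True)
class MHCAllele:
    name: str
    mhc_class: str

    @classmethod
    def from_name(cls, name: str) -> "MHCAllele":
        fam, norm = parse_hla_allele(name.split("/")[0]) if "/" not in name else (None, name)
        if fam is None:
            # paired alpha/beta chain name, e.g. HLA-DPA1*01:03/DPB1*04:01
            return cls(name, "II")
        return cls(norm, "I" if fam in CLASS_I_LOCI else "II")


def class_ii_alleles(haplotype) -> list[str]:
    """Prediction-ready class II allele names from a consensus haplotype.

    DRB alleles are used directly; HLA-DP needs an alpha/beta pair — if
    only one chain was called, DP is skipped with a warning.
    """
    alleles = haplotype.class_alleles("II")
    drb = [a for a in alleles if a.startswith("HLA-DRB")]
    dpa = [a for a in alleles if a.startswith("HLA-DPA")]
    dpb = [a for a in alleles if a.startswith("HLA-DPB")]
    out = list(drb)
    if dpa and dpb:
        out.extend(
            f"{a}/{b.removeprefix('HLA-')}" for a in sorted(dpa) for b in sorted(dpb)
        )
    elif dpa or dpb:
        log.warning("only one HLA-DP chain in the consensus haplotype; DP skipped")
    return sorted(out)


@dataclass(frozen=True)
class KmerQuery:
    """One mutant window to be assayed against one allele."""

    iar_id: str
    peptide: str
    allele: str
    wt_peptide: str | None = None


@dataclass(frozen=True)
class BindingPrediction:
    peptide: str
    allele: str
    percentile_rank: float
    method_ranks: tuple[float, ...]
    iar_id: str = ""
    wt_peptide: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.percentile_rank <= 100.0:
            raise RecordError(f"percentile rank {self.percentile_rank} outside [0, 100]")


@dataclass(frozen=True)
class EpitopeCall:
    """An accepted peptide:allele pair with optional wildtype comparison."""

    iar_id: str
    peptide: str
    allele: str
    mut_rank: float
    wt_peptide: str | None = None
    wt_rank: float | None = None


class Predictor(Protocol):
    """Pluggable percentile-rank predictor contract."""

    def method_ranks(self, peptide: str, allele: str) -> tuple[float, ...]:
        """Per-method percentile ranks in [0, 100] for one pair."""
        ...


class MockPredictor:
    """Deterministic stand-in for an external binding predictor.

    Ranks are derived from a seeded cryptographic hash of the
    (peptide, allele) pair, giving three pseudo-method percentiles that
    are uniform on [0, 100] and reproducible across platforms. In motif
    mode, peptides containing a planted anchor motif score below 1.0 so
    fixtures have guaranteed binders.
    """

    n_methods = 3

    def __init__(self, seed: int = 0, motifs: tuple[str, ...] = ()):
        self.seed = int(seed)
        self.motifs = tuple(motifs)

    def _uniform(self, peptide: str, allele: str, tag: int) -> float:
        digest = hashlib.blake2b(
            f"{peptide}|{allele}|{self.seed}|{tag}".encode(), digest_size=8
        ).digest()
        return int.from_bytes(digest, "big") / 2**64 * 100.0

    def method_ranks(self, peptide: str, allele: str) -> tuple[float, ...]:
        ranks = tuple(self._uniform(peptide, allele, i) for i in range(self.n_methods))
        if any(m in peptide for m in self.motifs):
            ranks = tuple(r / 100.0 * 0.99 for r in ranks)
        return ranks


def mock_predictor(seed: int = 0, motifs: tuple[str, ...] = ()) -> MockPredictor:
    return MockPredictor(seed=seed, motifs=motifs)


def enumerate_mutant_kmers(iar, n: int, alleles: list[str]) -> list[KmerQuery]:
    """All length-n windows of the IAR's mutant peptide covering >= 1 mutant position.

    The wildtype counterpart is the same window coordinates in the
    wildtype peptide, when one exists and is long enough.
    """
    mut = iar.mutant_peptide(n)
    if mut is None:
        return []
    wt = iar.wildtype_peptide(n)
    positions = set(iar.mutant_positions.get(n, ()))
    queries: list[KmerQuery] = []
    for start in range(0, len(mut) - n + 1):
        if not positions & set(range(start, start + n)):
            continue
        window = mut[start : start + n]
        wt_window = None
        if wt is not None and len(wt) >= start + n:
            wt_window = wt[start : start + n]
        for allele in alleles:
            queries.append(KmerQuery(iar.iar_id, window, allele, wt_window))
    return queries


def predict(queries: list[KmerQuery], predictor: Predictor) -> list[BindingPrediction]:
    """Consensus percentile (median of method percentiles) per query.

    A predictor failure for one pair is recorded and skipped, never
    silently dropped.
    """
    out: list[BindingPrediction] = []
    failures = 0
    for q in queries:
        try:
            ranks = tuple(predictor.method_ranks(q.peptide, q.allele))
        except Exception as exc:  # noqa: BLE001 - plug-in boundary
            failures += 1
            log.warning("predictor failed for %s:%s: %s", q.peptide, q.allele, exc)
            continue
        out.append(BindingPrediction(
            peptide=q.peptide, allele=q.allele,
            percentile_rank=float(statistics.median(ranks)),
            method_ranks=ranks, iar_id=q.iar_id, wt_peptide=q.wt_peptide,
        ))
    if failures:
        log.warning("predictor failed on %d of %d pairs", failures, len(queries))
    return out


def filter_binders(
    predictions: list[BindingPrediction],
    accept_threshold: float = 5.0,
    predictor: Predictor | None = None,
) -> list[EpitopeCall]:
    """Keep predictions in the top ``accept_threshold`` percent (inclusive).

    Only for accepted mutant peptides is the wildtype counterpart then
    assayed and attached, mirroring the two-stage assay design.
    """
    calls: list[EpitopeCall] = []
    for p in predictions:
        if p.percentile_rank > accept_threshold:
            continue
        wt_rank = None
        if p.wt_peptide is not None and predictor is not None:
            wt_rank = float(statistics.median(predictor.method_ranks(p.wt_peptide, p.allele)))
        calls.append(EpitopeCall(
            iar_id=p.iar_id, peptide=p.peptide, allele=p.allele,
            mut_rank=p.percentile_rank,
            wt_peptide=p.wt_peptide, wt_rank=wt_rank,
        ))
    return calls


def assay_iars(
    iars,
    class_i_alleles: list[str],
    class_ii_names: list[str],
    predictor: Predictor,
    accept_threshold: float = 5.0,
) -> dict[str, list[EpitopeCall]]:
    """Run the full enumerate -> predict -> filter chain per MHC class.

    Returns calls keyed by MHC class ("I" / "II").
    """
    queries_by_class: dict[str, list[KmerQuery]] = {"I": [], "II": []}
    for iar in iars:
        for n in (9, 10, 15):
            alleles = class_i_alleles if CLASS_OF_LENGTH[n] == "I" else class_ii_names
            queries_by_class[CLASS_OF_LENGTH[n]].extend(
                enumerate_mutant_kmers(iar, n, alleles)
            )
    out: dict[str, list[EpitopeCall]] = {}
    for mhc_class, queries in queries_by_class.items():
        predictions = predict(queries, predictor)
        out[mhc_class] = filter_binders(predictions, accept_threshold, predictor)
    return out
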