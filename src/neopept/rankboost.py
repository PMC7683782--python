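"""Feature-driven iterative rank boosting of immunoactive regions.

Candidates are first ordered by the best (lowest) percentile rank of any
contained epitope call. Each candidate then receives a boost in [0, 1]:
a weighted sum of per-feature scores, where a feature's score is its
within-run empirical quantile (higher feature value => higher score). For
three iterations, every candidate's provisional rank becomes
``old_rank * (1 - boost)`` and the table is re-sorted, so well-supported
regions bubble toward the top without ever leaving the candidate set.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

from scipy.stats import rankdata

from .errors import ConfigurationError

log = logging.getLogger(__name__)

FEATURE_NAMES = ("npa", "nph", "nmhc", "tpm", "nwt", "ovlp")

#: percentile-rank cutoff defining a "high binder" for the nph feature
STRONG_BINDER_RANK = 1.0


@dataclass(frozen=True)
class IARFeatures:
    """Per-region covariates feeding the boost.

    npa: accepted epitope calls from the region; nph: calls with
    percentile <= 1.0; nmhc: distinct alleles stimulated; tpm: combined
    isoform expression; nwt: calls binding better than their wildtype
    counterpart; ovlp: accepted 9-mer/10-mer nested pairs on one allele
    (class I only).
    """

    npa: int = 0
    nph: int = 0
    nmhc: int = 0
    tpm: float = 0.0
    nwt: int = 0
    ovlp: int = 0


@dataclass(frozen=True)
class BoostWeights:
    """Per-feature weights; each in [0, 1] with sum <= 1 so boost <= 1."""

    w_npa: float = 0.0
    w_nph: float = 0.0
    w_nmhc: float = 0.0
    w_tpm: float = 0.0
    w_nwt: float = 0.0
    w_ovlp: float = 0.0

    def __post_init__(self) -> None:
        vals = [getattr(self, f.name) for f in fields(self)]
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ConfigurationError(f"weights must lie in [0, 1]: {vals}")
        if sum(vals) > 1.0 + 1e-9:
            raise ConfigurationError(f"weight sum {sum(vals)} exceeds 1")

    def weight(self, feature: str) -> float:
        return getattr(self, f"w_{feature}")

    @classmethod
    def mhc_i_defaults(cls) -> "BoostWeights":
        """Overlap and promiscuity prioritized (0.68 / 0.32)."""
        return cls(w_ovlp=0.68, w_nmhc=0.32)

    @classmethod
    def mhc_ii_defaults(cls) -> "BoostWeights":
        """Five covariates equally important at 0.2 (no overlap for class II)."""
        return cls(w_npa=0.2, w_nph=0.2, w_nmhc=0.2, w_tpm=0.2, w_nwt=0.2)


@dataclass
class RankedIAR:
    iar_id: str
    features: IARFeatures
    boost: float
    initial_position: int
    final_position: int
    source_type: str = ""
    peptides: dict[int, str] = field(default_factory=dict)
    wt_peptides: dict[int, str] = field(default_factory=dict)


def compute_features(iar, calls, mhc_class: str) -> IARFeatures:
    """Count the region's covariates from its accepted epitope calls."""
    npa = len(calls)
    nph = sum(1 for c in calls if c.mut_rank <= STRONG_BINDER_RANK)
    nmhc = len({c.allele for c in calls})
    nwt = sum(1 for c in calls if c.wt_rank is not None and c.mut_rank < c.wt_rank)
    ovlp = 0
    if mhc_class == "I":
        nines = [c for c in calls if len(c.peptide) == 9]
        tens = [c for c in calls if len(c.peptide) == 10]
        for c9 in nines:
            for c10 in tens:
                if c9.allele == c10.allele and c9.peptide in c10.peptide:
                    ovlp += 1
    return IARFeatures(npa=npa, nph=nph, nmhc=nmhc, tpm=float(iar.tpm),
                       nwt=nwt, ovlp=ovlp)


@dataclass
class Candidate:
    """One region entering the ranking, with its best call percentile."""

    iar_id: str
    features: IARFeatures
    best_rank: float
    source_type: str = ""
    peptides: dict[int, str] = field(default_factory=dict)
    wt_peptides: dict[int, str] = field(default_factory=dict)


def make_candidates(iars, calls_by_iar: dict[str, list], mhc_class: str) -> list["Candidate"]:
    out = []
    for iar in iars:
        calls = calls_by_iar.get(iar.iar_id, [])
        if not calls:
            continue
        peptides = {n: iar.mutant_peptide(n) for n in (9, 10, 15) if iar.mutant_peptide(n)}
        wt = {n: iar.wildtype_peptide(n) for n in (9, 10, 15) if iar.wildtype_peptide(n)}
        out.append(Candidate(
            iar_id=iar.iar_id,
            features=compute_features(iar, calls, mhc_class),
            best_rank=min(c.mut_rank for c in calls),
            source_type=iar.source_type, peptides=peptides, wt_peptides=wt,
        ))
    return out


def initial_order(candidates: list[Candidate]) -> list[Candidate]:
    """Best (lowest) contained percentile first; ties by npa then id."""
    usable = []
    for c in candidates:
        if c.features.npa == 0:
            log.warning("candidate %s has no accepted calls; excluded", c.iar_id)
            continue
        usable.append(c)
    return sorted(usable, key=lambda c: (c.best_rank, -c.features.npa, c.iar_id))


def feature_scores(candidates: list[Candidate]) -> list[dict[str, float]]:
    """Within-run empirical quantile of each feature, in [0, 1].

    With m candidates the score is (average-tied ascending rank - 1) /
    (m - 1); a single candidate scores 0. Scores depend only on the
    ordering of feature values, not their scale.
    """
    m = len(candidates)
    scores: list[dict[str, float]] = [dict() for _ in candidates]
    for name in FEATURE_NAMES:
        values = [getattr(c.features, name) for c in candidates]
        if m == 1:
            ranks = [1.0]
        else:
            ranks = rankdata(values, method="average")
        for i, r in enumerate(ranks):
            scores[i][name] = 0.0 if m == 1 else (float(r) - 1.0) / (m - 1)
    return scores


def boost_ranks(
    candidates: list[Candidate],
    weights: BoostWeights,
    iterations: int = 3,
) -> list[RankedIAR]:
    """Three passes of ``new_rank = old_rank * (1 - boost)`` with re-sorting.

    Feature scores (hence boosts) are computed once and stay constant;
    each pass multiplies the current integer position by (1 - boost) and
    re-sorts ascending, breaking ties by better best-percentile then id.
    """
    ordered = initial_order(candidates)
    if not ordered:
        return []
    scores = feature_scores(ordered)
    boosts = [
        sum(weights.weight(name) * s[name] for name in FEATURE_NAMES)
        for s in scores
    ]
    initial_pos = {c.iar_id: i + 1 for i, c in enumerate(ordered)}
    table = list(zip(ordered, boosts))
    for _ in range(iterations):
        keyed = [
            (pos * (1.0 - boost), cand.best_rank, cand.iar_id, cand, boost)
            for pos, (cand, boost) in enumerate(table, start=1)
        ]
        keyed.sort(key=lambda t: (t[0], t[1], t[2]))
        table = [(cand, boost) for _, _, _, cand, boost in keyed]
    return [
        RankedIAR(
            iar_id=cand.iar_id, features=cand.features, boost=boost,
            initial_position=initial_pos[cand.iar_id], final_position=pos,
            source_type=cand.source_type, peptides=cand.peptides,
            wt_peptides=cand.wt_peptides,
        )
        for pos, (cand, boost) in enumerate(table, start=1)
    ]
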