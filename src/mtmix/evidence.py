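"""Likelihood-ratio calculus for mtDNA mixture evidence.

Evidence is weighed as LR = P(E | H_num) / P(E | H_den) for an explicitly
stated pair of hypotheses.  Because mtDNA is a single non-recombining marker,
hypotheses concern *lineages*, never individuals: every maternal relative
shares the haplotype.  Frequencies are plain counting proportions from a
haplotype database, kept as exact rationals; the only correction offered is
the add-one convention for an unseen haplotype (regarded as favorable to the
defendant).

Also provided: the probability that an m-contributor mixture is informative
(not all contributors sharing one haplotype), and the clinical
contamination-versus-instability LR comparing a somatic-mutation explanation
of x heteroplasmic positions against contamination by a known haplotype.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational
from typing import Sequence

import numpy as np

from .errors import NormalizationError, ParameterError
from .profiles import (
    HaplotypeDatabase,
    Profile,
    UnseenPolicy,
    format_profile,
    frequency,
)


@dataclass
class LRResult:
    """A likelihood ratio with its hypothesis labels and per-term detail.

    Likelihoods are kept exact (:class:`~fractions.Fraction`) whenever the
    inputs are rational; ``lr`` exposes the ratio in whatever arithmetic the
    likelihoods carry and ``lr_float``/``log10_lr`` give float renderings.
    """

    label_num: str
    label_den: str
    likelihood_num: Fraction | float
    likelihood_den: Fraction | float
    detail: dict = field(default_factory=dict)
    status: str = "ok"

    @property
    def lr(self) -> Fraction | float:
        if self.likelihood_den == 0:
            raise ZeroDivisionError("denominator likelihood is zero")
        if self.likelihood_num == 0:
            return (
                Fraction(0)
                if isinstance(self.likelihood_den, Rational)
                else 0.0
            )
        return self.likelihood_num / self.likelihood_den

    @property
    def lr_float(self) -> float:
        return float(self.lr)

    @property
    def log10_lr(self) -> float:
        lr = self.lr
        if lr == 0:
            return float("-inf")
        if isinstance(lr, Rational):
            # exact log for huge rationals that overflow float
            return (
                math.log10(lr.numerator) - math.log10(lr.denominator)
            )
        return math.log10(lr)


def _as_fraction(p) -> Fraction | float:
    if isinstance(p, Rational):
        return Fraction(p)
    return float(p)


def lr_known_contributor(
    db: HaplotypeDatabase | None = None,
    suspect_profile: Profile | None = None,
    unseen_policy: UnseenPolicy = UnseenPolicy.ADD_ONE,
    suspect_frequency=None,
    label_num: str = "H_P: mixture = known contributor's lineage + suspect's lineage",
    label_den: str = "H_D: mixture = known contributor's lineage + an unknown lineage",
) -> LRResult:
    """LR for a mixture with one known contributor (e.g. a typed victim) and
    the suspect's lineage asserted only under the numerator.

    LR = 1/p where p is the counting-proportion frequency of the suspect
    haplotype; p may be supplied directly via ``suspect_frequency`` (e.g. a
    published estimate) instead of a database lookup.
    """
    if suspect_frequency is None:
        if db is None or suspect_profile is None:
            raise ParameterError(
                "need a database and suspect profile, or an explicit "
                "suspect_frequency"
            )
        p = frequency(db, suspect_profile, unseen_policy)
    else:
        p = _as_fraction(suspect_frequency)
    if not 0 < p <= 1:
        raise ParameterError(f"suspect frequency {p} outside (0, 1]")
    detail = {"suspect_frequency": p}
    if suspect_profile is not None:
        detail["suspect_profile"] = format_profile(suspect_profile)
    return LRResult(
        label_num=label_num,
        label_den=label_den,
        likelihood_num=Fraction(1) if isinstance(p, Rational) else 1.0,
        likelihood_den=p,
        detail=detail,
    )


def lr_two_unknown(
    db: HaplotypeDatabase | None = None,
    pair: Sequence[Profile] | None = None,
    unseen_policy: UnseenPolicy = UnseenPolicy.ERROR,
    pair_frequencies=None,
    unordered_factor: int = 2,
    label_num: str = "H_P: mixture = the two named lineages",
    label_den: str = "H_D: mixture = two random lineages",
) -> LRResult:
    """LR for a specific unordered pair of lineages against two independent
    draws from the database frequencies.

    With distinct profiles the denominator is ``unordered_factor * p1 * p2``
    (both orderings of an iid draw; the factor is switchable to 1 for an
    ordered-draw convention); with identical profiles it is p^2.  The
    numerator likelihood is 1: the named pair explains the stain.
    """
    if pair_frequencies is not None:
        p1, p2 = (_as_fraction(p) for p in pair_frequencies)
        distinct = pair is None or pair[0] != pair[1]
        if pair is not None:
            distinct = pair[0] != pair[1]
    else:
        if db is None or pair is None or len(pair) != 2:
            raise ParameterError(
                "need a database and a pair of profiles, or explicit "
                "pair_frequencies"
            )
        p1 = frequency(db, pair[0], unseen_policy)
        p2 = frequency(db, pair[1], unseen_policy)
        distinct = pair[0] != pair[1]
    if distinct:
        den = unordered_factor * p1 * p2
    else:
        den = p1 * p2
    if den == 0:
        raise ParameterError("zero denominator likelihood")
    if den > 1:
        den = _as_fraction(1) if isinstance(den, Rational) else 1.0
    return LRResult(
        label_num=label_num,
        label_den=label_den,
        likelihood_num=Fraction(1) if isinstance(den, Rational) else 1.0,
        likelihood_den=den,
        detail={
            "p1": p1,
            "p2": p2,
            "distinct_profiles": distinct,
            "unordered_factor": unordered_factor if distinct else 1,
        },
    )


def _check_freqs(freqs: Sequence) -> list:
    total = sum(freqs)
    if abs(float(total) - 1.0) > 1e-9:
        raise NormalizationError(
            f"frequencies sum to {float(total)!r}, not 1"
        )
    if any(p < 0 for p in freqs):
        raise NormalizationError("negative frequency")
    return list(freqs)


def prob_informative(freqs: Sequence, m: int):
    """Probability that m iid draws from haplotype frequencies p_1..p_k are
    not all identical: 1 - sum_j p_j^m.

    A mixture of identical profiles is unidentifiable; this is the chance a
    random m-person mixture is detectable at all given the database.
    """
    if m < 2:
        raise ParameterError(f"m={m}: an informative mixture needs m >= 2")
    freqs = _check_freqs(freqs)
    exact = all(isinstance(p, Rational) for p in freqs)
    same = sum(Fraction(p) ** m if exact else float(p) ** m for p in freqs)
    one = Fraction(1) if exact else 1.0
    return one - same


@dataclass
class MCEstimate:
    """Monte-Carlo probability estimate with its binomial standard error."""

    estimate: float
    se: float
    n_sims: int


def prob_informative_mc(
    db: HaplotypeDatabase, m: int, n_sims: int, seed: int
) -> MCEstimate:
    """Simulation estimate of :func:`prob_informative` from database draws."""
    if m < 2:
        raise ParameterError(f"m={m}: an informative mixture needs m >= 2")
    if n_sims < 1:
        raise ParameterError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    probs = np.array(
        [float(f) for f in db.frequencies().values()], dtype=float
    )
    draws = rng.choice(len(probs), size=(n_sims, m), p=probs)
    informative = (draws != draws[:, [0]]).any(axis=1)
    p_hat = float(informative.mean())
    se = math.sqrt(p_hat * (1.0 - p_hat) / n_sims)
    return MCEstimate(estimate=p_hat, se=se, n_sims=n_sims)


class SiteModel(enum.Enum):
    """Null model for where x somatic mutations fall among S candidate
    phylogenetic sites: independent uniform placement, or a uniformly chosen
    set of x distinct sites."""

    INDEPENDENT_UNIFORM = "independent_uniform"
    DISTINCT_SITES = "distinct_sites"


@dataclass
class ContaminationScenario:
    """Inputs of the clinical contamination-vs-instability comparison.

    S: number of phylogenetic sites at which a somatic mutation could occur
    (no default: choosing a conservative lower limit is the caller's call).
    x: number of observed heteroplasmic/mutated positions.
    p_c: population frequency of the single contaminating haplotype that the
    deconvolution identified; for several candidate haplotypes supply
    ``candidate_frequencies`` instead (the numerator is their sum), and an
    empty candidate list means no haplotype explains the pattern, so the
    contamination hypothesis is dismissed outright.
    """

    S: int
    x: int
    p_c: Fraction | float | None = None
    candidate_frequencies: Sequence | None = None
    site_model: SiteModel = SiteModel.INDEPENDENT_UNIFORM

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ParameterError(f"S={self.S} must be >= 1")
        if not 1 <= self.x <= self.S:
            raise ParameterError(
                f"x={self.x} must satisfy 1 <= x <= S={self.S}"
            )
        if self.p_c is not None and not 0 < self.p_c <= 1:
            raise ParameterError(f"p_c={self.p_c} outside (0, 1]")


def mutation_likelihood(scenario: ContaminationScenario):
    """Likelihood of x somatic mutations under the instability hypothesis.

    INDEPENDENT_UNIFORM (the default: mutations occur independently and
    uniformly over the S sites) gives (1/S)^x; DISTINCT_SITES (x distinct
    positions drawn uniformly) gives 1/C(S, x).
    """
    if scenario.site_model is SiteModel.INDEPENDENT_UNIFORM:
        return Fraction(1, scenario.S) ** scenario.x
    if scenario.x > scenario.S:
        raise ParameterError("x > S impossible under DISTINCT_SITES")
    return Fraction(1, math.comb(scenario.S, scenario.x))


def contamination_lr(scenario: ContaminationScenario) -> LRResult:
    """LR in favor of contamination over genuine somatic instability.

    Numerator: the frequency of the contaminating haplotype (or the sum over
    candidate haplotypes consistent with the mixture).  Denominator: the
    mutation likelihood under the chosen site model.  With no candidate
    haplotype at all the contamination hypothesis is dismissed without
    calculation (LR = 0).
    """
    label_num = "H_2: the data result from contamination of the patient profile"
    label_den = "H_1: the data are the patient profile with tumor mutations"
    if scenario.candidate_frequencies is not None:
        candidates = list(scenario.candidate_frequencies)
        if not candidates:
            return LRResult(
                label_num=label_num,
                label_den=label_den,
                likelihood_num=Fraction(0),
                likelihood_den=mutation_likelihood(scenario),
                detail={"n_candidates": 0},
                status=(
                    "no haplotype combination is consistent with the data; "
                    "the contamination hypothesis is dismissed"
                ),
            )
        num = sum(_as_fraction(p) for p in candidates)
        detail = {"n_candidates": len(candidates)}
    elif scenario.p_c is not None:
        num = _as_fraction(scenario.p_c)
        detail = {"p_c": num}
    else:
        raise ParameterError(
            "scenario needs p_c or a candidate_frequencies list"
        )
    den = mutation_likelihood(scenario)
    detail.update(
        {
            "S": scenario.S,
            "x": scenario.x,
            "site_model": scenario.site_model.value,
            "mutation_likelihood": den,
        }
    )
    return LRResult(
        label_num=label_num,
        label_den=label_den,
        likelihood_num=num,
        likelihood_den=den,
        detail=detail,
    )
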