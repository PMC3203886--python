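"""Categorical mixture deconvolution.

Given a stain coded per position as reference-only / variant-only / mixed and
a haplotype database assumed to contain every plausible contributor, find all
m-contributor combinations of distinct database profiles consistent with the
stain.  Consistency assumes no dropout and no drop-in: a MIXED position must
be explained by at least one carrier and one non-carrier, a VARIANT_ONLY
position by every contributor carrying the variant, and a REF_ONLY position by
no contributor carrying it.

A search has three possible outcomes — no solution, a unique solution, or
several — and the enumeration is deliberately exhaustive; candidate sets
should still be reviewed for phylogenetic plausibility, which no algorithm
here attempts.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ParameterError
from .profiles import (
    HaplotypeDatabase,
    MixtureObservation,
    Profile,
    SiteStatus,
    format_profile,
)

#: Exhaustive search guards; override with ``allow_large=True``.
MAX_CONTRIBUTORS = 4
MAX_DISTINCT_PROFILES = 10_000

#: Advisory appended to reports: candidate sets need expert phylogenetic
#: review, which is outside the scope of this search.
PHYLOGENY_ADVISORY = (
    "Candidate contributor sets are combinatorial only; review each set for "
    "phylogenetic plausibility before reporting."
)


@dataclass(frozen=True)
class DeconvolutionSolution:
    """An unordered multiset of contributor profiles consistent with a stain."""

    contributors: tuple[Profile, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "contributors", tuple(sorted(self.contributors))
        )

    @property
    def m(self) -> int:
        return len(self.contributors)

    def key(self) -> tuple[tuple[int, ...], ...]:
        return tuple(p.key() for p in self.contributors)

    def __str__(self) -> str:
        return " + ".join(format_profile(p) for p in self.contributors)


class SearchStatus(enum.Enum):
    NO_SOLUTION = "no_solution"
    UNIQUE = "unique"
    MULTIPLE = "multiple"


@dataclass
class SearchOutcome:
    """Result of a deconvolution search: status plus all solutions found."""

    solutions: list[DeconvolutionSolution] = field(default_factory=list)

    @property
    def status(self) -> SearchStatus:
        if not self.solutions:
            return SearchStatus.NO_SOLUTION
        if len(self.solutions) == 1:
            return SearchStatus.UNIQUE
        return SearchStatus.MULTIPLE


def is_consistent(
    contributors: Sequence[Profile],
    obs: MixtureObservation,
    known: Sequence[Profile] | None = None,
) -> bool:
    """No-dropout/no-drop-in consistency of a contributor multiset with a
    stain.

    For every position: MIXED requires at least one contributor carrying the
    variant and at least one carrying the reference base; VARIANT_ONLY
    requires all contributors to carry the variant; REF_ONLY (explicit or
    implicit) requires that none do.
    """
    contributors = list(contributors)
    if not contributors:
        raise ParameterError("need at least one contributor")
    if known:
        pool = list(contributors)
        for prof in known:
            if prof in pool:
                pool.remove(prof)
            else:
                return False
    n = len(contributors)
    # every contributor variant must be visible in the stain
    for prof in contributors:
        for pos in prof.positions:
            if obs.status(pos) is SiteStatus.REF_ONLY:
                return False
    for pos, status in obs.sites.items():
        carriers = sum(1 for prof in contributors if prof.carries(pos))
        if status is SiteStatus.MIXED:
            if not 0 < carriers < n:
                return False
        elif status is SiteStatus.VARIANT_ONLY:
            if carriers != n:
                return False
        else:  # explicit REF_ONLY
            if carriers != 0:
                return False
    return True


def _check_guards(m: int, k: int, allow_large: bool) -> None:
    if m < 1:
        raise ParameterError(f"contributor count m={m} must be >= 1")
    if not allow_large and (m > MAX_CONTRIBUTORS or k > MAX_DISTINCT_PROFILES):
        raise ParameterError(
            f"exhaustive search refused for m={m}, k={k} distinct profiles "
            f"(limits m<={MAX_CONTRIBUTORS}, k<={MAX_DISTINCT_PROFILES}); "
            "pass allow_large=True to override"
        )


def enumerate_contributors(
    db: HaplotypeDatabase,
    obs: MixtureObservation,
    m: int,
    known: Sequence[Profile] = (),
    allow_large: bool = False,
) -> SearchOutcome:
    """Exhaustively enumerate all consistent unordered m-multisets of distinct
    database profiles.

    ``known`` profiles (for example a typed victim) are fixed members of every
    candidate set; they constrain the search rather than having their signal
    subtracted.  Identical contributor profiles are admitted only when the
    stain has no mixed position (an unidentifiable mixture); with a mixed
    position present they can never satisfy consistency.  Solutions are
    returned in lexicographic order of sorted variant positions.
    """
    known = list(known)
    if len(known) > m:
        raise ParameterError(f"{len(known)} known contributors but m={m}")
    distinct = db.distinct_profiles()
    _check_guards(m, len(distinct), allow_large)
    free = m - len(known)
    seen: set = set()
    solutions: list[DeconvolutionSolution] = []
    for extra in itertools.combinations_with_replacement(distinct, free):
        candidate = DeconvolutionSolution(tuple(known) + extra)
        if candidate.key() in seen:
            continue
        seen.add(candidate.key())
        if is_consistent(candidate.contributors, obs, known=known):
            solutions.append(candidate)
    solutions.sort(key=DeconvolutionSolution.key)
    return SearchOutcome(solutions)


def superset_solutions(
    db: HaplotypeDatabase,
    obs: MixtureObservation,
    base_solution: DeconvolutionSolution | Sequence[Profile],
    m_extra: int,
    allow_large: bool = False,
) -> list[DeconvolutionSolution]:
    """All consistent enlargements of a base solution by up to ``m_extra``
    database profiles.

    Documents the more-than-m-contributor ambiguity: any haplotype whose
    alleles coincide with the base contributors' outside the mixed sites can
    be added without changing the categorical data.  Includes the base
    solution itself (the zero-extra case).
    """
    if isinstance(base_solution, DeconvolutionSolution):
        base = list(base_solution.contributors)
    else:
        base = list(base_solution)
    if m_extra < 0:
        raise ParameterError("m_extra must be >= 0")
    distinct = db.distinct_profiles()
    _check_guards(len(base) + m_extra, len(distinct), allow_large)
    seen: set = set()
    out: list[DeconvolutionSolution] = []
    for n_extra in range(m_extra + 1):
        for extra in itertools.combinations_with_replacement(distinct, n_extra):
            candidate = DeconvolutionSolution(tuple(base) + extra)
            if candidate.key() in seen:
                continue
            seen.add(candidate.key())
            if is_consistent(candidate.contributors, obs):
                out.append(candidate)
    out.sort(key=lambda s: (s.m, s.key()))
    return out
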