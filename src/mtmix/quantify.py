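"""Quantitative two-contributor deconvolution from scaled peak heights.

When the variant peak height y1 at each site is available (scaled so that
y0 + y1 = 1), a mixture of two haploid contributors with variant indicator
vectors x1, x2 and mixing fraction beta satisfies

    y_i = beta * x1_i + (1 - beta) * x2_i + eps_i,

which rewrites to the one-parameter no-intercept regression

    y_i - x2_i = beta * (x1_i - x2_i) + eps_i.

The least-squares estimate has the closed form

    beta_hat = sum_i (y_i - x2_i)(x1_i - x2_i) / sum_i (x1_i - x2_i)^2,

with standard error, t-test of "contributor j did not contribute"
(H0: beta = 0 or beta = 1), and the conventional R-squared used to rank
competing contributor pairs: the most likely pair is the one whose model fits
best.  Sites where the indicators agree (x1 = x2) carry no information about
beta but are retained, contributing to noise-variance estimation and to the
sums of squares, mirroring the full quantitative site table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .deconvolve import DeconvolutionSolution
from .errors import DegenerateModelError, ParameterError
from .profiles import (
    MixtureObservation,
    Profile,
    design_matrix,
    design_sites,
    format_profile,
)

#: Candidate pairs whose R-squared differ by less than this are reported as
#: an unresolved tie rather than broken arbitrarily.
R2_TIE_TOLERANCE = 1e-9


@dataclass(frozen=True)
class TwoContributorModel:
    """An ordered candidate pair with its binary site design.

    ``sites`` is the ordered site list (positions, optionally preceded by the
    ``"rCRS"`` pseudo-site row of the quantitative table); ``x1``/``x2`` are
    the haploid variant indicators of the two contributors over those sites.
    """

    profile1: Profile
    profile2: Profile
    sites: tuple
    x1: np.ndarray = field(compare=False)
    x2: np.ndarray = field(compare=False)

    @classmethod
    def build(
        cls,
        profile1: Profile,
        profile2: Profile,
        sites: Sequence | None = None,
        extra_sites: Sequence[int] = (),
        include_reference_site: bool = False,
    ) -> "TwoContributorModel":
        if sites is None:
            sites = design_sites(
                (profile1, profile2),
                extra=extra_sites,
                include_reference_site=include_reference_site,
            )
        mat = design_matrix((profile1, profile2), sites)
        return cls(
            profile1=profile1,
            profile2=profile2,
            sites=tuple(sites),
            x1=mat[:, 0].astype(float),
            x2=mat[:, 1].astype(float),
        )

    def swapped(self) -> "TwoContributorModel":
        """The same unordered pair with contributor roles exchanged."""
        return TwoContributorModel(
            profile1=self.profile2,
            profile2=self.profile1,
            sites=self.sites,
            x1=self.x2.copy(),
            x2=self.x1.copy(),
        )

    @property
    def pair_label(self) -> str:
        return f"{format_profile(self.profile1)} | {format_profile(self.profile2)}"


@dataclass
class FractionEstimate:
    """Least-squares mixture-fraction estimate for one candidate pair."""

    beta_hat: float
    se: float
    r_squared: float
    p_value_beta0: float
    n_sites: int
    flags: list[str] = field(default_factory=list)

    @property
    def out_of_range(self) -> bool:
        return "beta_out_of_range" in self.flags


def peaks_vector(obs: MixtureObservation, sites: Sequence) -> np.ndarray:
    """Align the observation's peak heights to an ordered site list."""
    if obs.peaks is None:
        raise ParameterError("observation carries no peak heights")
    try:
        return np.array([float(obs.peaks[s]) for s in sites])
    except KeyError as exc:
        raise ParameterError(f"no peak height for site {exc.args[0]}") from exc


def _as_y(obs, model: TwoContributorModel) -> np.ndarray:
    if isinstance(obs, MixtureObservation):
        return peaks_vector(obs, model.sites)
    y = np.asarray(obs, dtype=float)
    if y.shape != model.x1.shape:
        raise ParameterError(
            f"peak vector length {y.shape} does not match {len(model.sites)} sites"
        )
    return y


def estimate_fraction(
    obs: MixtureObservation | Sequence[float],
    model: TwoContributorModel,
) -> FractionEstimate:
    """Closed-form least-squares estimate of the fraction contributed by
    contributor 1, with standard error, fit and the t-test of beta = 0.

    ``obs`` may be a :class:`MixtureObservation` with peaks covering the model
    sites, or a bare peak-height vector aligned to them.
    """
    y = _as_y(obs, model)
    w = model.x1 - model.x2
    denom = float(w @ w)
    if denom == 0.0:
        raise DegenerateModelError(
            "contributor profiles identical over the model sites; the "
            "fraction is unidentifiable"
        )
    beta = float(w @ (y - model.x2)) / denom
    fitted = beta * model.x1 + (1.0 - beta) * model.x2
    resid = y - fitted
    n = len(y)
    ss_res = float(resid @ resid)
    df = n - 1
    flags: list[str] = []
    if df <= 0:
        se = float("nan")
        p = float("nan")
        flags.append("insufficient_sites")
    else:
        sigma2 = ss_res / df
        se = float(np.sqrt(sigma2 / denom))
        if se == 0.0:
            p = 1.0 if beta == 0.0 else 0.0
        else:
            t = beta / se
            p = 2.0 * float(stats.t.sf(abs(t), df))
    r2 = _r_squared(y, fitted, flags)
    if not 0.0 <= beta <= 1.0:
        flags.append("beta_out_of_range")
    return FractionEstimate(
        beta_hat=beta,
        se=se,
        r_squared=r2,
        p_value_beta0=p,
        n_sites=n,
        flags=flags,
    )


def _r_squared(y: np.ndarray, fitted: np.ndarray, flags: list[str]) -> float:
    """Centered R^2 = 1 - SS_res/SS_tot, clipped to [0, 1] with a flag."""
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        flags.append("degenerate_fit")
        return 0.0
    r2 = 1.0 - ss_res / ss_tot
    if r2 < 0.0:
        flags.append("fit_worse_than_mean")
        return 0.0
    return min(r2, 1.0)


def model_fit(
    obs: MixtureObservation | Sequence[float],
    model: TwoContributorModel,
) -> float:
    """Conventional R-squared of the fitted two-contributor model."""
    return estimate_fraction(obs, model).r_squared


def test_no_contribution(
    obs: MixtureObservation | Sequence[float],
    model: TwoContributorModel,
    contributor_index: int = 1,
) -> float:
    """Two-sided p-value for "contributor j did not contribute".

    For contributor 1 the null is beta = 0; for contributor 2 it is beta = 1
    (equivalently, fraction 0 for that contributor). Uses the regression
    t-statistic with n_sites - 1 degrees of freedom.
    """
    if contributor_index not in (1, 2):
        raise ParameterError("contributor_index must be 1 or 2")
    est = estimate_fraction(obs, model)
    beta0 = 0.0 if contributor_index == 1 else 1.0
    df = est.n_sites - 1
    if df <= 0:
        return float("nan")
    if est.se == 0.0:
        return 1.0 if est.beta_hat == beta0 else 0.0
    t = (est.beta_hat - beta0) / est.se
    return 2.0 * float(stats.t.sf(abs(t), df))


@dataclass
class RankedHypothesis:
    model: TwoContributorModel
    estimate: FractionEstimate


@dataclass
class RankingResult:
    """Candidate pairs ordered by model fit (largest R-squared first)."""

    entries: list[RankedHypothesis]
    unresolved: bool = False

    @property
    def best(self) -> RankedHypothesis:
        return self.entries[0]


def _as_model(candidate, sites) -> TwoContributorModel:
    if isinstance(candidate, TwoContributorModel):
        return candidate
    if isinstance(candidate, DeconvolutionSolution):
        profs = candidate.contributors
    else:
        profs = tuple(candidate)
    if len(profs) != 2:
        raise ParameterError(
            f"quantitative model is strictly two-contributor, got {len(profs)}"
        )
    return TwoContributorModel.build(profs[0], profs[1], sites=sites)


def rank_hypotheses(
    obs: MixtureObservation | Sequence[float],
    candidates: Sequence,
    sites: Sequence | None = None,
) -> RankingResult:
    """Rank competing contributor pairs by R-squared, descending.

    Candidates may be :class:`TwoContributorModel` instances, deconvolution
    solutions, or bare profile pairs (the latter two are given a common site
    design).  Pairs whose fits differ by less than ``R2_TIE_TOLERANCE`` are
    reported as an unresolved tie, not broken arbitrarily.
    """
    if not candidates:
        raise ParameterError("no candidate pairs to rank")
    models = [_as_model(c, sites) for c in candidates]
    entries = [
        RankedHypothesis(m, estimate_fraction(obs, m)) for m in models
    ]
    entries.sort(key=lambda e: -e.estimate.r_squared)
    unresolved = any(
        abs(a.estimate.r_squared - b.estimate.r_squared) < R2_TIE_TOLERANCE
        for a, b in zip(entries, entries[1:])
    )
    return RankingResult(entries=entries, unresolved=unresolved)
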