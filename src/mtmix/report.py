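"""Rendering of result objects as text, TSV or JSON.

Floats are printed with 6 significant digits; likelihood ratios additionally
as log10.  JSON output for LR results and search outcomes round-trips to an
identical object (exact rational likelihoods are serialized as "p/q"
strings).
"""

from __future__ import annotations

import json
from fractions import Fraction
from numbers import Rational

from .deconvolve import (
    PHYLOGENY_ADVISORY,
    DeconvolutionSolution,
    SearchOutcome,
    SearchStatus,
)
from .evidence import LRResult, MCEstimate
from .profiles import format_profile, parse_profile
from .quantify import FractionEstimate, RankingResult
from .simulate import StudySummary

#: Shown when a search finds nothing: the usual causes are contamination or a
#: non-exhaustive database rather than a truly inexplicable stain.
NO_SOLUTION_NOTE = (
    "No consistent combination found. Consider problems relating to "
    "contamination and the database not being exhaustive."
)


def sig6(x: float) -> str:
    return f"{float(x):.6g}"


def _frac(v) -> str:
    if isinstance(v, Rational):
        return f"{v.numerator}/{v.denominator}"
    return sig6(v)


def render_lr_text(result: LRResult) -> str:
    lines = [
        f"numerator   {result.label_num}",
        f"denominator {result.label_den}",
        f"P(E|H_num) = {_frac(result.likelihood_num)}",
        f"P(E|H_den) = {_frac(result.likelihood_den)}",
        f"LR = {sig6(result.lr_float)}",
        f"log10(LR) = {sig6(result.log10_lr)}",
    ]
    if result.status != "ok":
        lines.append(f"status: {result.status}")
    return "\n".join(lines)


def lr_to_dict(result: LRResult) -> dict:
    def enc(v):
        if isinstance(v, Rational):
            return f"{v.numerator}/{v.denominator}"
        return v

    return {
        "type": "LRResult",
        "label_num": result.label_num,
        "label_den": result.label_den,
        "likelihood_num": enc(result.likelihood_num),
        "likelihood_den": enc(result.likelihood_den),
        "status": result.status,
        "lr": result.lr_float if result.likelihood_den else None,
        "log10_lr": result.log10_lr,
        "detail": {k: enc(v) for k, v in result.detail.items()},
    }


def _dec(v):
    if isinstance(v, str) and "/" in v and v.replace("/", "").isdigit():
        return Fraction(v)
    return v


def lr_from_dict(data: dict) -> LRResult:
    return LRResult(
        label_num=data["label_num"],
        label_den=data["label_den"],
        likelihood_num=_dec(data["likelihood_num"]),
        likelihood_den=_dec(data["likelihood_den"]),
        status=data.get("status", "ok"),
        detail={k: _dec(v) for k, v in data.get("detail", {}).items()},
    )


def render_outcome_text(outcome: SearchOutcome) -> str:
    lines = [f"status: {outcome.status.value}"]
    if outcome.status is SearchStatus.NO_SOLUTION:
        lines.append(NO_SOLUTION_NOTE)
    for i, sol in enumerate(outcome.solutions, start=1):
        lines.append(f"solution {i}: {sol}")
    if outcome.solutions:
        lines.append(PHYLOGENY_ADVISORY)
    return "\n".join(lines)


def render_outcome_tsv(outcome: SearchOutcome) -> str:
    lines = ["solution\tcontributors"]
    for i, sol in enumerate(outcome.solutions, start=1):
        lines.append(f"{i}\t{sol}")
    lines.append(f"# status: {outcome.status.value}")
    if outcome.status is SearchStatus.NO_SOLUTION:
        lines.append(f"# {NO_SOLUTION_NOTE}")
    return "\n".join(lines)


def outcome_to_dict(outcome: SearchOutcome) -> dict:
    return {
        "type": "SearchOutcome",
        "status": outcome.status.value,
        "solutions": [
            {
                "contributors": [
                    format_profile(p) for p in sol.contributors
                ],
                "range": [
                    sol.contributors[0].range_start,
                    sol.contributors[0].range_end,
                ],
            }
            for sol in outcome.solutions
        ],
    }


def outcome_from_dict(data: dict) -> SearchOutcome:
    solutions = []
    for sol in data["solutions"]:
        lo, hi = sol.get("range", (16024, 16365))
        solutions.append(
            DeconvolutionSolution(
                tuple(parse_profile(s, lo, hi) for s in sol["contributors"])
            )
        )
    return SearchOutcome(solutions)


def render_estimate_tsv(pair_label: str, est: FractionEstimate) -> str:
    header = "pair\tbeta_hat\tse\tr_squared\tp_beta0\tn_sites\tflags"
    row = "\t".join(
        [
            pair_label,
            sig6(est.beta_hat),
            sig6(est.se),
            sig6(est.r_squared),
            sig6(est.p_value_beta0),
            str(est.n_sites),
            ",".join(est.flags) or "-",
        ]
    )
    return f"{header}\n{row}"


def render_ranking_tsv(ranking: RankingResult) -> str:
    lines = ["rank\tpair\tbeta_hat\tse\tr_squared\tp_beta0\tflags"]
    for rank, entry in enumerate(ranking.entries, start=1):
        est = entry.estimate
        lines.append(
            "\t".join(
                [
                    str(rank),
                    entry.model.pair_label,
                    sig6(est.beta_hat),
                    sig6(est.se),
                    sig6(est.r_squared),
                    sig6(est.p_value_beta0),
                    ",".join(est.flags) or "-",
                ]
            )
        )
    if ranking.unresolved:
        lines.append("# tie: top fits are indistinguishable (unresolved)")
    return "\n".join(lines)


def render_summary_text(summary: StudySummary) -> str:
    return "\n".join(
        [
            f"n_sims = {summary.n_sims}",
            f"correct_rate = {sig6(summary.correct_rate)}",
            f"beta_mean = {sig6(summary.beta_mean)}",
            f"beta_q025 = {sig6(summary.beta_q025)}",
            f"beta_q975 = {sig6(summary.beta_q975)}",
            f"sigma = {sig6(summary.sigma)}",
            f"dropout = {sig6(summary.dropout)}",
            f"drop_in = {sig6(summary.drop_in)}",
            f"seed = {summary.seed}",
        ]
    )


def render_mc_text(mc: MCEstimate) -> str:
    return (
        f"estimate = {sig6(mc.estimate)}\n"
        f"binomial_se = {sig6(mc.se)}\n"
        f"n_sims = {mc.n_sims}"
    )


def write_report(result, format: str = "text") -> str:
    """Render any result object in the requested format."""
    if format == "json":
        if isinstance(result, LRResult):
            return json.dumps(lr_to_dict(result), indent=2)
        if isinstance(result, SearchOutcome):
            return json.dumps(outcome_to_dict(result), indent=2)
        raise TypeError(f"no JSON rendering for {type(result).__name__}")
    if isinstance(result, LRResult):
        return render_lr_text(result)
    if isinstance(result, SearchOutcome):
        return (
            render_outcome_tsv(result)
            if format == "tsv"
            else render_outcome_text(result)
        )
    if isinstance(result, RankingResult):
        return render_ranking_tsv(result)
    if isinstance(result, StudySummary):
        return render_summary_text(result)
    if isinstance(result, MCEstimate):
        return render_mc_text(result)
    raise TypeError(f"no rendering for {type(result).__name__}")
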