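"""Data model and parsing for rCRS-relative mtDNA haplotype profiles.

An mtDNA lineage over a typed sequence range (by default HVS-I, positions
16024-16365) is represented as the set of positions at which it differs from
the revised Cambridge Reference Sequence (rCRS).  A bare position number in a
profile string denotes a transition with respect to the rCRS base at that
position (A<->G, C<->T); the explicit ``T16304C`` notation records ref and alt
bases and also admits transversions.  A stain (possibly a mixture) is encoded
per position as reference-only, variant-only, or mixed, the last carried by an
IUPAC ambiguity suffix such as ``16189Y``; optionally each site carries a
scaled variant peak height ``y1`` with ``y0 + y1 = 1``.

Profile identity — for database collapsing, frequency counting and
deconvolution — is the set of variant *positions*: ``16093`` and ``C16093T``
name the same lineage.
"""

from __future__ import annotations

import csv
import enum
import re
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    DatabaseError,
    DuplicatePositionError,
    EmptyDatabaseError,
    PositionRangeError,
    ProfileFormatError,
    ProfileNotFoundError,
    ReferenceMismatchWarning,
)

#: Default typed range: HVS-I as printed in the reference database excerpt.
DEFAULT_RANGE = (16024, 16365)

#: Label of the pseudo-site marking the reference haplotype row in the
#: quantitative site table (the row that is 1 only for the rCRS profile).
REFERENCE_SITE = "rCRS"

TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: IUPAC ambiguity codes -> set of bases. Two-base codes encode a mixed site;
#: codes covering more than two bases are accepted but flagged.
IUPAC_CODES = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_PROFILE_TOKEN = re.compile(r"^([ACGT])?(\d+)([ACGT])?$", re.IGNORECASE)
_MIXTURE_TOKEN = re.compile(r"^(\d+)([A-Z]?)$", re.IGNORECASE)


def rcrs_reference() -> dict[int, str]:
    """Curated rCRS bases at commonly reported control-region positions."""
    table: dict[int, str] = {}
    text = resources.files("mtmix.data").joinpath("rcrs_sites.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("position"):
            continue
        pos, base = line.split("\t")
        table[int(pos)] = base.upper()
    return table


_RCRS: dict[int, str] | None = None


def _reference() -> dict[int, str]:
    global _RCRS
    if _RCRS is None:
        _RCRS = rcrs_reference()
    return _RCRS


@dataclass(frozen=True, order=True)
class VariantSite:
    """A single difference from the rCRS.

    ``ref_base``/``alt_base`` are optional annotation: a bare-number transition
    at a position missing from the curated reference table stores neither.
    """

    position: int
    ref_base: str | None = field(default=None, compare=False)
    alt_base: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.ref_base is not None and self.ref_base == self.alt_base:
            raise ProfileFormatError(
                f"ref and alt base identical at {self.position}"
            )

    def token(self) -> str:
        if self.ref_base is not None and self.alt_base is not None:
            return f"{self.ref_base}{self.position}{self.alt_base}"
        return str(self.position)


class Profile:
    """One mtDNA lineage: a set of variant sites over a declared range.

    The empty set is a valid profile and denotes the rCRS itself. Equality and
    hashing are by the set of variant positions, so base-annotated and bare
    spellings of the same lineage compare equal.
    """

    __slots__ = ("variants", "range_start", "range_end")

    def __init__(
        self,
        variants: Iterable[VariantSite | int] = (),
        range_start: int = DEFAULT_RANGE[0],
        range_end: int = DEFAULT_RANGE[1],
    ) -> None:
        sites = []
        for v in variants:
            if not isinstance(v, VariantSite):
                v = _transition_site(int(v))
            sites.append(v)
        positions = [s.position for s in sites]
        if len(set(positions)) != len(positions):
            raise DuplicatePositionError(f"duplicate positions in {positions}")
        for p in positions:
            if not range_start <= p <= range_end:
                raise PositionRangeError(
                    f"position {p} outside range [{range_start}, {range_end}]"
                )
        self.variants = frozenset(sites)
        self.range_start = range_start
        self.range_end = range_end

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(s.position for s in self.variants)

    def key(self) -> tuple[int, ...]:
        """Canonical identity: the sorted tuple of variant positions."""
        return tuple(sorted(s.position for s in self.variants))

    def carries(self, position: int) -> bool:
        return position in self.positions

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Profile):
            return NotImplemented
        return self.key() == other.key()

    def __hash__(self) -> int:
        return hash(self.key())

    def __lt__(self, other: "Profile") -> bool:
        return self.key() < other.key()

    def __len__(self) -> int:
        return len(self.variants)

    def __repr__(self) -> str:
        return f"Profile({format_profile(self)!r})"


def _transition_site(position: int) -> VariantSite:
    ref = _reference().get(position)
    alt = TRANSITION_PARTNER[ref] if ref is not None else None
    return VariantSite(position, ref, alt)


def parse_profile(
    text: str,
    range_start: int = DEFAULT_RANGE[0],
    range_end: int = DEFAULT_RANGE[1],
) -> Profile:
    """Parse a profile string such as ``"16093 16189 16293"`` or ``"rCRS"``.

    Tokens are whitespace-separated; each is ``rCRS`` (alone, the empty
    profile), a bare position (implying a transition), or letter-flanked like
    ``T16304C`` (explicit ref/alt, admitting transversions).
    """
    tokens = text.split()
    if len(tokens) == 1 and tokens[0].lower() == "rcrs":
        return Profile((), range_start, range_end)
    sites: list[VariantSite] = []
    for tok in tokens:
        if tok.lower() == "rcrs":
            raise ProfileFormatError(
                f"'rCRS' must stand alone, got {text!r}"
            )
        m = _PROFILE_TOKEN.match(tok)
        if m is None:
            raise ProfileFormatError(f"unparseable profile token {tok!r}")
        ref, pos_s, alt = m.groups()
        if (ref is None) != (alt is None):
            raise ProfileFormatError(
                f"token {tok!r} must be bare or letter-flanked like T16304C"
            )
        position = int(pos_s)
        if ref is None:
            sites.append(_transition_site(position))
        else:
            ref, alt = ref.upper(), alt.upper()
            known = _reference().get(position)
            if known is not None and known != ref:
                warnings.warn(
                    f"token {tok!r}: stated ref base {ref} differs from the "
                    f"rCRS base {known} at {position}",
                    ReferenceMismatchWarning,
                    stacklevel=2,
                )
            sites.append(VariantSite(position, ref, alt))
    return Profile(sites, range_start, range_end)


def format_profile(profile: Profile) -> str:
    """Canonical string for a profile; inverse of :func:`parse_profile`."""
    if not profile.variants:
        return "rCRS"
    sites = sorted(profile.variants, key=lambda s: s.position)
    out = []
    for s in sites:
        ref = _reference().get(s.position)
        # bare spelling when the token is the implied transition
        if s.ref_base is None or (
            ref == s.ref_base and s.alt_base == TRANSITION_PARTNER.get(ref)
        ):
            out.append(str(s.position))
        else:
            out.append(s.token())
    return " ".join(out)


class SiteStatus(enum.Enum):
    """Per-position status of a stain."""

    REF_ONLY = "ref_only"
    VARIANT_ONLY = "variant_only"
    MIXED = "mixed"


@dataclass
class MixtureObservation:
    """Per-position categorical status of a stain, optionally with scaled
    variant peak heights.

    ``sites`` records only non-reference positions; everything else is
    implicitly REF_ONLY.  ``peaks`` maps a site label (a position, or the
    ``"rCRS"`` pseudo-site of the quantitative table) to the scaled variant
    peak height ``y1`` in [0, 1].
    """

    sites: dict[int, SiteStatus] = field(default_factory=dict)
    peaks: dict[int | str, float] | None = None
    mixed_bases: dict[int, str] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    range_start: int = DEFAULT_RANGE[0]
    range_end: int = DEFAULT_RANGE[1]

    def __post_init__(self) -> None:
        for pos in self.sites:
            if not self.range_start <= pos <= self.range_end:
                raise PositionRangeError(
                    f"stain position {pos} outside "
                    f"[{self.range_start}, {self.range_end}]"
                )
        if self.peaks is not None:
            for label, y1 in self.peaks.items():
                if not 0.0 <= y1 <= 1.0:
                    raise ProfileFormatError(
                        f"peak height {y1} at {label} outside [0, 1]"
                    )

    def status(self, position: int) -> SiteStatus:
        return self.sites.get(position, SiteStatus.REF_ONLY)

    @property
    def mixed_positions(self) -> frozenset[int]:
        return frozenset(
            p for p, s in self.sites.items() if s is SiteStatus.MIXED
        )

    @property
    def variant_only_positions(self) -> frozenset[int]:
        return frozenset(
            p for p, s in self.sites.items() if s is SiteStatus.VARIANT_ONLY
        )

    @classmethod
    def from_contributors(
        cls,
        contributors: Sequence[Profile],
        range_start: int | None = None,
        range_end: int | None = None,
    ) -> "MixtureObservation":
        """Noise-free categorical observation generated by a contributor set:
        positions carried by all contributors are VARIANT_ONLY, by some but
        not all MIXED, by none REF_ONLY."""
        if not contributors:
            raise ProfileFormatError("need at least one contributor")
        rs = range_start or contributors[0].range_start
        re_ = range_end or contributors[0].range_end
        sites: dict[int, SiteStatus] = {}
        union = set().union(*(p.positions for p in contributors))
        for pos in union:
            n = sum(1 for p in contributors if p.carries(pos))
            sites[pos] = (
                SiteStatus.VARIANT_ONLY
                if n == len(contributors)
                else SiteStatus.MIXED
            )
        return cls(sites=sites, range_start=rs, range_end=re_)


def parse_mixture(
    text: str,
    range_start: int = DEFAULT_RANGE[0],
    range_end: int = DEFAULT_RANGE[1],
    strict: bool = False,
) -> MixtureObservation:
    """Parse a stain string such as ``"16126Y 16292Y 16294Y 16304Y 16399R"``.

    A position with an IUPAC ambiguity suffix is MIXED; a bare position is
    VARIANT_ONLY; every other position is implicitly REF_ONLY.  Two-base codes
    are decoded (``Y`` = C/T, ``R`` = A/G); when neither decoded base matches
    the rCRS base at that position a :class:`ReferenceMismatchWarning` is
    emitted (raised as an error when ``strict``). Codes spanning more than two
    bases are accepted and flagged.
    """
    sites: dict[int, SiteStatus] = {}
    mixed_bases: dict[int, str] = {}
    obs_flags: list[str] = []
    for tok in text.split():
        m = _MIXTURE_TOKEN.match(tok)
        if m is None:
            raise ProfileFormatError(f"unparseable stain token {tok!r}")
        position = int(m.group(1))
        suffix = m.group(2).upper()
        if position in sites:
            raise DuplicatePositionError(f"duplicate stain position {position}")
        if not suffix:
            sites[position] = SiteStatus.VARIANT_ONLY
            continue
        if suffix not in IUPAC_CODES:
            raise ProfileFormatError(
                f"stain token {tok!r}: {suffix!r} is not an IUPAC "
                "ambiguity code"
            )
        bases = IUPAC_CODES[suffix]
        sites[position] = SiteStatus.MIXED
        mixed_bases[position] = bases
        if len(bases) > 2:
            obs_flags.append(f"{position}{suffix}: >2-base ambiguity code")
        ref = _reference().get(position)
        if ref is not None and len(bases) == 2 and ref not in bases:
            msg = (
                f"stain token {tok!r}: code {suffix} = {'/'.join(bases)} does "
                f"not include the rCRS base {ref} at {position}"
            )
            if strict:
                raise ProfileFormatError(msg)
            warnings.warn(msg, ReferenceMismatchWarning, stacklevel=2)
    obs = MixtureObservation(
        sites=sites,
        mixed_bases=mixed_bases,
        flags=obs_flags,
        range_start=range_start,
        range_end=range_end,
    )
    return obs


def load_mixture(
    path,
    range_start: int = DEFAULT_RANGE[0],
    range_end: int = DEFAULT_RANGE[1],
) -> MixtureObservation:
    """Read a stain file: either one line of tokens, or two columns
    ``token  y1`` per line (``y1`` optional; the ``rCRS`` pseudo-site row of a
    quantitative table is admitted)."""
    lines = [
        ln.strip()
        for ln in open(path, encoding="utf-8")
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if len(lines) == 1 and "\t" not in lines[0]:
        return parse_mixture(lines[0], range_start, range_end)
    tokens: list[str] = []
    peaks: dict[int | str, float] = {}
    for ln in lines:
        parts = ln.split()
        tok = parts[0]
        if tok.lower() in ("site", "token", "position"):
            continue  # header
        if len(parts) > 1:
            label: int | str = (
                REFERENCE_SITE if tok.lower() == "rcrs" else int(re.match(r"\d+", tok).group())
            )
            peaks[label] = float(parts[1])
        if tok.lower() != "rcrs":
            tokens.append(tok)
    obs = parse_mixture(" ".join(tokens), range_start, range_end)
    if peaks:
        obs.peaks = peaks
        obs.__post_init__()
    return obs


class UnseenPolicy(enum.Enum):
    """How to handle a frequency query for a profile absent from the
    database: refuse, or add the query profile once before counting (the
    convention regarded as favorable to the defendant)."""

    ERROR = "error"
    ADD_ONE = "add_one"


class HaplotypeDatabase:
    """A collection of observed profiles with counts.

    Identical profiles under different sample ids collapse to one distinct
    profile whose count is the number of observations; frequencies are plain
    counting proportions.
    """

    def __init__(self, entries: Iterable[tuple[str, Profile]]) -> None:
        self.entries: list[tuple[str, Profile]] = list(entries)
        self._counts: dict[Profile, int] = {}
        for _, prof in self.entries:
            self._counts[prof] = self._counts.get(prof, 0) + 1

    @classmethod
    def from_counts(
        cls, pairs: Iterable[tuple[Profile, int]]
    ) -> "HaplotypeDatabase":
        entries = []
        i = 0
        for prof, count in pairs:
            for _ in range(count):
                i += 1
                entries.append((f"S{i}", prof))
        return cls(entries)

    @property
    def total(self) -> int:
        return len(self.entries)

    @property
    def k(self) -> int:
        """Number of distinct profiles."""
        return len(self._counts)

    def distinct_profiles(self) -> list[Profile]:
        """Distinct profiles in deterministic (lexicographic) order."""
        return sorted(self._counts)

    def count(self, profile: Profile) -> int:
        return self._counts.get(profile, 0)

    def __contains__(self, profile: Profile) -> bool:
        return profile in self._counts

    def __len__(self) -> int:
        return self.total

    def frequencies(self) -> dict[Profile, Fraction]:
        """Counting-proportion frequency of every distinct profile."""
        return {
            p: Fraction(c, self.total) for p, c in sorted(self._counts.items())
        }

    def all_positions(self) -> list[int]:
        """Sorted union of variant positions over the distinct profiles."""
        pos: set[int] = set()
        for p in self._counts:
            pos |= p.positions
        return sorted(pos)


def load_database(
    path,
    delimiter: str | None = None,
    header: str | bool = "auto",
    range_start: int = DEFAULT_RANGE[0],
    range_end: int = DEFAULT_RANGE[1],
) -> HaplotypeDatabase:
    """Load a TSV/CSV haplotype database with columns
    (region, sample_id, profile)."""
    if delimiter is None:
        delimiter = "," if str(path).lower().endswith(".csv") else "\t"
    entries: list[tuple[str, Profile]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if row[0].lstrip().startswith("#"):
                continue
            if lineno == 1 and header in ("auto", True):
                joined = " ".join(row).lower()
                if header is True or "profile" in joined or "sample" in joined:
                    continue
            if len(row) < 3:
                raise DatabaseError(
                    f"{path}: line {lineno}: expected 3 columns "
                    f"(region, sample_id, profile), got {len(row)}"
                )
            sample_id = row[1].strip()
            try:
                prof = parse_profile(row[2].strip(), range_start, range_end)
            except Exception as exc:
                raise DatabaseError(
                    f"{path}: line {lineno}: {exc}"
                ) from exc
            entries.append((sample_id, prof))
    if not entries:
        raise EmptyDatabaseError(f"{path}: no profile rows found")
    return HaplotypeDatabase(entries)


def frequency(
    db: HaplotypeDatabase,
    profile: Profile,
    unseen_policy: UnseenPolicy = UnseenPolicy.ERROR,
) -> Fraction:
    """Counting-proportion frequency of ``profile`` in ``db``.

    Under ``ADD_ONE`` the query profile is added once to the database before
    counting, so an unseen profile gets 1/(total+1) and every other profile's
    frequency uses the denominator total+1.
    """
    count = db.count(profile)
    if unseen_policy is UnseenPolicy.ADD_ONE:
        return Fraction(count + 1, db.total + 1)
    if count == 0:
        raise ProfileNotFoundError(
            f"profile {format_profile(profile)!r} not in database "
            "(unseen_policy=ERROR)"
        )
    return Fraction(count, db.total)


def design_matrix(
    profiles: Sequence[Profile],
    sites: Sequence[int | str],
) -> np.ndarray:
    """Binary site-by-profile indicator matrix.

    Entry (i, j) is 1 iff profile j carries the variant at site i.  The label
    ``"rCRS"`` denotes the pseudo-site of the quantitative table whose row
    marks the reference haplotype itself (1 only for the empty profile).
    """
    mat = np.zeros((len(sites), len(profiles)), dtype=int)
    for i, site in enumerate(sites):
        for j, prof in enumerate(profiles):
            if site == REFERENCE_SITE:
                mat[i, j] = 1 if len(prof) == 0 else 0
            else:
                mat[i, j] = 1 if prof.carries(int(site)) else 0
    return mat


def design_sites(
    profiles: Sequence[Profile],
    extra: Sequence[int] = (),
    include_reference_site: bool = False,
) -> list[int | str]:
    """Ordered site list for a design: sorted union of the profiles' variant
    positions plus any explicitly requested positions, optionally preceded by
    the ``"rCRS"`` pseudo-site row."""
    pos: set[int] = set(extra)
    for p in profiles:
        pos |= p.positions
    sites: list[int | str] = sorted(pos)
    if include_reference_site:
        sites.insert(0, REFERENCE_SITE)
    return sites
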