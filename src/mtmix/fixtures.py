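"""Packaged datasets: the HVS-I database excerpt, its quantitative recoding
with one realized peak-height column, and the two worked case inputs.

Everything ships inside the package as plain text; nothing is downloaded.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .profiles import (
    HaplotypeDatabase,
    MixtureObservation,
    Profile,
    load_database,
    parse_mixture,
    parse_profile,
)

FIXTURE_FILES = {
    "table1_excerpt": "table1_excerpt.tsv",
    "table2_quant": "table2_quant.tsv",
    "example1_stain": "example1_stain.txt",
    "example3_case": "example3_case.txt",
    "rcrs_sites": "rcrs_sites.tsv",
}


def list_fixtures() -> list[str]:
    return sorted(FIXTURE_FILES)


def fixture_text(name: str) -> str:
    try:
        fname = FIXTURE_FILES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(list_fixtures())}"
        ) from None
    return resources.files("mtmix.data").joinpath(fname).read_text()


def fixture_path(name: str) -> Path:
    """Materialize a fixture to a real file path (for CLI-style use)."""
    text = fixture_text(name)
    out = Path(tempfile.gettempdir()) / f"mtmix_{FIXTURE_FILES[name]}"
    out.write_text(text)
    return out


def table1_database() -> HaplotypeDatabase:
    """The nine printed rows of the HVS-I excerpt; identical profiles under
    different sample ids collapse, giving 8 distinct profiles of total 9."""
    with resources.as_file(
        resources.files("mtmix.data").joinpath("table1_excerpt.tsv")
    ) as path:
        return load_database(path)


def table1_profiles() -> dict[str, Profile]:
    """Profiles of the excerpt keyed by haplotype name (H20, H21, ...)."""
    db = table1_database()
    return {f"H{sample_id}": prof for sample_id, prof in db.entries}


def _table2_rows() -> list[list[str]]:
    rows = []
    for line in fixture_text("table2_quant").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def table2_sites() -> list:
    """The 11 ordered site labels of the quantitative table (the reference
    pseudo-site row first, then positions)."""
    rows = _table2_rows()
    return [r[0] if r[0] == "rCRS" else int(r[0]) for r in rows[1:]]


def table2_matrix() -> tuple[list[str], np.ndarray]:
    """(haplotype names, 0/1 indicator matrix) as printed."""
    rows = _table2_rows()
    names = rows[0][1:-1]
    mat = np.array([[int(v) for v in r[1:-1]] for r in rows[1:]], dtype=int)
    return names, mat


def table2_y() -> np.ndarray:
    """The realized peak-height column y1 (mixture of H22 at 0.3 and H23)."""
    rows = _table2_rows()
    return np.array([float(r[-1]) for r in rows[1:]])


def table2_observation() -> MixtureObservation:
    """The quantitative table as a mixture observation: categorical statuses
    of the generating H22+H23 mixture, with the realized peak heights."""
    profs = table1_profiles()
    obs = MixtureObservation.from_contributors((profs["H22"], profs["H23"]))
    obs.peaks = dict(zip(table2_sites(), table2_y()))
    return obs


def example1_stain() -> MixtureObservation:
    """Stain with the 16093 variant in full and mixed bases at 16189/16293."""
    lines = [
        ln.strip()
        for ln in fixture_text("example1_stain").splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    return parse_mixture(lines[0])


@dataclass(frozen=True)
class CaseProfiles:
    victim: Profile
    suspect: Profile
    mixture: MixtureObservation
    range_start: int
    range_end: int


def example3_case() -> CaseProfiles:
    """The cigarette-butt murder case: typed victim, suspect and stain."""
    fields: dict[str, str] = {}
    rng = (16024, 16569)
    for line in fixture_text("example3_case").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("\t")
        if key == "range":
            lo, hi = value.split("\t")
            rng = (int(lo), int(hi))
        else:
            fields[key] = value.replace("\t", " ")
    return CaseProfiles(
        victim=parse_profile(fields["victim"], *rng),
        suspect=parse_profile(fields["suspect"], *rng),
        mixture=parse_mixture(fields["mixture"], *rng),
        range_start=rng[0],
        range_end=rng[1],
    )
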