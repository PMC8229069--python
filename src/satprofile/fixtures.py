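"""Packaged study fixtures and family configurations.

The CON2 fixture encodes the fully text-reconstructable worked example of the
source study: 8 alteration columns over 13 accessions falling into four
profile groups (sizes 4/6/2/1), with the reference consensus heterozygous at
columns {1,3,4,5,8} and homozygous at {2,6,7}.  Zygosity structure follows the
study; base identities and column positions are synthetic conventions, flagged
as such in the packaged JSON.

The CON1-style and COM2-style configurations reproduce what the study states
about those families — 11 (resp. 9) alteration columns, the shared
D. antarctica/D. parvula profile with triplet heterozygous states in four
accessions (CON1), and all-unique profiles over six samples (COM2) — with
otherwise synthetic detail.
"""

from __future__ import annotations

import csv
import json
from importlib import resources

from .grouping import GroupPartition
from .profiling import ProfileMatrix
from .synthetic import FamilyConfig, PlantedColumn

CON2_SAMPLES = (
    "D. antarctica KEW-0522816",
    "D. antarctica KEW-0661919",
    "D. antarctica KEW-0521613",
    "D. parvula",
    "D. sukatschewii",
    "D. cespitosa PI-562652",
    "D. cespitosa PI-577069",
    "D. cespitosa PI-371724",
    "D. elongata",
    "D. flexuosa",
    "H. pubescens",
    "K. macrantha",
    "D. danthonioides",
)

#: CON1 was likewise obtained for 13 accessions; same panel as CON2.
CON1_SAMPLES = CON2_SAMPLES

#: The six accessions with clean COM2 amplicons.
COM2_SAMPLES = (
    "D. cespitosa PI-577069",
    "D. cespitosa PI-562652",
    "D. parvula",
    "D. flexuosa",
    "K. macrantha",
    "T. phleoides",
)

#: Accessions whose CON1 consensi carry triplet (three-base) heterozygous states.
CON1_TRIPLET_SAMPLES = (
    "D. sukatschewii",
    "D. cespitosa PI-371724",
    "D. cespitosa PI-562652",
    "H. pubescens",
)


def _data_text(name: str) -> str:
    return resources.files("satprofile.data").joinpath(name).read_text()


def load_accessions() -> dict[str, dict[str, str]]:
    """Study accession metadata (species, catalog number, origin) by label."""
    reader = csv.DictReader(_data_text("accessions.tsv").splitlines(), delimiter="\t")
    return {row["label"]: row for row in reader}


def con2_fixture(seed: int = 0) -> FamilyConfig:
    """The CON2 worked-example configuration, loaded from the packaged JSON."""
    spec = json.loads(_data_text("con2_fixture.json"))
    member_states: dict[str, dict[int, str]] = {}
    for group in spec["groups"]:
        for member in group["members"]:
            member_states[member] = {int(k): v for k, v in group["states"].items()}
    columns = []
    for col in spec["columns"]:
        states = {
            acc: by_col[col["index"]]
            for acc, by_col in member_states.items()
            if col["index"] in by_col
        }
        columns.append(
            PlantedColumn(
                position=col["position"],
                ref_allele=col["ref_allele"],
                alt_allele=col["alt_allele"],
                reference_state=col["reference_state"],
                states=states,
            )
        )
    accessions = tuple(m for g in spec["groups"] for m in g["members"])
    assert set(accessions) == set(CON2_SAMPLES)
    return FamilyConfig(
        family=spec["family"], accessions=accessions, columns=tuple(columns), seed=seed
    )


def con2_expected_partition() -> GroupPartition:
    """The four-group partition the CON2 fixture must reproduce."""
    spec = json.loads(_data_text("con2_fixture.json"))
    matrix = con2_expected_matrix()
    from .grouping import Group  # local import to avoid cycle at module load

    groups = []
    for g in spec["groups"]:
        groups.append(
            Group(members=list(g["members"]), representative_profile=matrix.profile(g["members"][0]))
        )
    return GroupPartition(groups=groups)


def con2_expected_matrix() -> ProfileMatrix:
    """The expected CON2 profile matrix, from the packaged TSV."""
    return ProfileMatrix.from_tsv(_data_text("con2_fixture.tsv"))


def _extra_allele(r: str, a: str) -> str:
    return min(set("ACGT") - {r, a})


_ALLELE_CYCLE = [
    ("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("A", "T"),
    ("C", "G"), ("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("A", "T"),
]


def con1_triplet_config(seed: int = 0) -> FamilyConfig:
    """A CON1-style configuration: 11 columns over the 13-accession panel.

    The three D. antarctica accessions and D. parvula share a profile except
    that KEW-0521613 carries one extra alteration; the other nine accessions
    have unique profiles; the four triplet accessions carry a three-base state.
    """
    trio = CON1_SAMPLES[:2] + (CON1_SAMPLES[3],)  # KEW-0522816, KEW-0661919, D. parvula
    distinct = CON1_SAMPLES[2]  # KEW-0521613
    others = tuple(s for s in CON1_SAMPLES if s not in trio and s != distinct)
    n_cols = 11
    length = 333
    positions = [k * length // (n_cols + 1) for k in range(1, n_cols + 1)]
    columns = []
    for k in range(n_cols):
        r, a = _ALLELE_CYCLE[k]
        states: dict[str, str] = {}
        if k == 0:
            states = {acc: "het" for acc in trio + (distinct,)}
        elif k == 1:
            states = {distinct: "het"}
        else:
            owner = others[k - 2]
            for acc in others:
                states[acc] = "hom_alt"
            states[owner] = "het3" if owner in CON1_TRIPLET_SAMPLES else "het"
        columns.append(
            PlantedColumn(
                position=positions[k],
                ref_allele=r,
                alt_allele=a,
                extra_allele=_extra_allele(r, a),
                states=states,
            )
        )
    return FamilyConfig(
        family="CON1", accessions=CON1_SAMPLES, columns=tuple(columns), seed=seed
    )


def com2_unique_config(seed: int = 0) -> FamilyConfig:
    """A COM2-style configuration: 9 columns, six samples, all profiles unique."""
    n_cols = 9
    length = 322
    positions = [k * length // (n_cols + 1) for k in range(1, n_cols + 1)]
    columns = []
    for k in range(n_cols):
        r, a = _ALLELE_CYCLE[k]
        states: dict[str, str] = {}
        if k < 6:
            states[COM2_SAMPLES[k]] = "hom_alt"
        else:
            states[COM2_SAMPLES[k - 6]] = "het"
        columns.append(
            PlantedColumn(
                position=positions[k],
                ref_allele=r,
                alt_allele=a,
                extra_allele=_extra_allele(r, a),
                states=states,
            )
        )
    return FamilyConfig(
        family="COM2", accessions=COM2_SAMPLES, columns=tuple(columns), seed=seed
    )


FIXTURE_CONFIGS = {
    "con2": con2_fixture,
    "con1_triplet": con1_triplet_config,
    "com2_unique": com2_unique_config,
}
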