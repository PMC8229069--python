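"""Seeded generator of IUPAC-coded consensus FASTA with planted alteration profiles.

Emulates Sanger consensus sequences of satellite-monomer PCR fragments: a
pseudo-random reference monomer of the family's fragment length, per-accession
copies carrying planted column states (homozygous substitutions, two-base
heterozygous codes, three-base "triplet" codes), optional primer flanks
attached outside the homologous core, and optional background substitution /
indel noise.  Every record is accompanied by a machine-readable truth table,
consistent with the FASTA by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .iupac import base_set, clean_sequence, encode_set

#: Published fragment lengths (bp) of the three families' PCR products.
FAMILY_LENGTHS = {"CON1": 333, "CON2": 538, "COM2": 322}

#: The one primer pair printed in the source protocol (COM1_F1 / COM1_R1),
#: reused as neutral flank material for all families.
PRIMER_F = "CGGGATAGTACACTTTGGAC"
PRIMER_R = "GGAGACCGATGGATTTTC"

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def default_flanks() -> tuple[str, str]:
    """(left, right) flank: forward primer and reverse-complemented reverse primer."""
    return PRIMER_F, revcomp(PRIMER_R)


#: Per-accession state names for a planted column.
#:   ref      — copy the reference state (no alteration at this column)
#:   hom_ref  — homozygous reference allele {r}
#:   hom_alt  — homozygous alternative allele {a}
#:   het      — heterozygous {r, a}
#:   het_alt  — heterozygous without the reference {a, extra}
#:   het3     — triplet {r, a, extra}
STATE_NAMES = ("ref", "hom_ref", "hom_alt", "het", "het_alt", "het3")


@dataclass(frozen=True)
class PlantedColumn:
    """One planted alteration column of a family configuration."""

    position: int  # 0-based on the reference core
    ref_allele: str
    alt_allele: str
    extra_allele: str | None = None  # third base for het3 / het_alt
    reference_state: str = "hom_ref"  # "hom_ref" or "het": state in the reference row
    states: dict[str, str] = field(default_factory=dict, hash=False)  # accession -> name

    def state_code(self, name: str) -> str:
        r, a = self.ref_allele, self.alt_allele
        if name == "ref":
            name = self.reference_state
        if name == "hom_ref":
            return r
        if name == "hom_alt":
            return a
        if name == "het":
            return encode_set({r, a})
        if name == "het_alt":
            if self.extra_allele is None:
                raise ValueError(f"column at {self.position}: het_alt needs extra_allele")
            return encode_set({a, self.extra_allele})
        if name == "het3":
            if self.extra_allele is None:
                raise ValueError(f"column at {self.position}: het3 needs extra_allele")
            return encode_set({r, a, self.extra_allele})
        raise ValueError(f"unknown state name {name!r}")

    def reference_code(self) -> str:
        return self.state_code(self.reference_state)


@dataclass(frozen=True)
class FamilyConfig:
    """Study conditions for one simulated family dataset."""

    family: str
    accessions: tuple[str, ...]
    columns: tuple[PlantedColumn, ...] = ()
    length: int | None = None  # defaults to the family's fragment length
    seed: int = 0
    left_flank: str | None = None
    right_flank: str | None = None
    background_rate: float = 0.0
    indel_rate: float = 0.0

    def __post_init__(self):
        if self.length is None:
            try:
                object.__setattr__(self, "length", FAMILY_LENGTHS[self.family])
            except KeyError:
                raise ValueError(
                    f"unknown family {self.family!r}: give an explicit length"
                ) from None
        if self.length <= 0:
            raise ValueError("reference length must be positive")
        for rate in (self.background_rate, self.indel_rate):
            if not (0.0 <= rate < 1.0):
                raise ValueError("rates must lie in [0, 1)")
        positions = [c.position for c in self.columns]
        if len(set(positions)) != len(positions):
            raise ValueError("planted positions must be unique")
        for c in self.columns:
            if not (0 <= c.position < self.length):
                if self.left_flank or self.right_flank:
                    raise ValueError(
                        f"planted position {c.position} collides with a flank or lies "
                        f"outside the {self.length} bp homologous core"
                    )
                raise ValueError(
                    f"planted position {c.position} outside [0, {self.length})"
                )
            for acc in c.states:
                if acc not in self.accessions:
                    raise ValueError(f"state for unknown accession {acc!r}")
            for name in c.states.values():
                if name not in STATE_NAMES:
                    raise ValueError(f"unknown state name {name!r}")


@dataclass
class TruthTable:
    """What was planted where, per accession; consistent with the emitted FASTA."""

    family: str
    reference: str
    planted_positions: list[int]
    states: dict[str, dict[int, str]]  # accession -> position -> emitted code
    flank_lengths: tuple[int, int]
    background_positions: dict[str, list[int]]
    indels: dict[str, list[tuple[int, str]]]  # (position, "del" | "ins:<base>")

    def to_tsv(self) -> str:
        lines = [
            f"# family: {self.family}",
            f"# flanks: {self.flank_lengths[0]} {self.flank_lengths[1]}",
            "accession\tposition\tcode\tkind",
        ]
        for acc in sorted(self.states):
            for pos in self.planted_positions:
                lines.append(f"{acc}\t{pos}\t{self.states[acc][pos]}\tplanted")
            for pos in self.background_positions.get(acc, []):
                lines.append(f"{acc}\t{pos}\t.\tbackground")
            for pos, kind in self.indels.get(acc, []):
                lines.append(f"{acc}\t{pos}\t.\t{kind}")
        return "\n".join(lines) + "\n"


def _rng(config: FamilyConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), *stream])


def make_reference(config: FamilyConfig) -> str:
    """Pseudo-random canonical-base reference carrying the planted reference states.

    Reproducible from the config seed; heterozygous reference columns carry the
    corresponding two-base ambiguity code.
    """
    rng = _rng(config, 0)
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=config.length))
    for col in config.columns:
        seq[col.position] = col.reference_code()
    return "".join(seq)


def generate_dataset(config: FamilyConfig) -> tuple[list[tuple[str, str]], TruthTable]:
    """Emit one consensus record per accession plus the matching truth table.

    Each record is the reference with that accession's planted column states
    substituted, background noise applied at the configured rates (never on a
    planted column, so the truth table stays exact), and flanks attached
    outside the homologous core.
    """
    reference = make_reference(config)
    left = clean_sequence(config.left_flank, "left flank") if config.left_flank else ""
    right = clean_sequence(config.right_flank, "right flank") if config.right_flank else ""
    planted = sorted(c.position for c in config.columns)
    planted_set = set(planted)
    free_positions = np.array(
        [p for p in range(config.length) if p not in planted_set], dtype=int
    )

    records: list[tuple[str, str]] = []
    states: dict[str, dict[int, str]] = {}
    bg: dict[str, list[int]] = {}
    indels: dict[str, list[tuple[int, str]]] = {}
    for k, acc in enumerate(config.accessions):
        rng = _rng(config, 1, k)
        seq = list(reference)
        states[acc] = {}
        for col in sorted(config.columns, key=lambda c: c.position):
            code = col.state_code(col.states.get(acc, "ref"))
            seq[col.position] = code
            states[acc][col.position] = code
        bg_pos: list[int] = []
        if config.background_rate > 0 and len(free_positions):
            n_mut = rng.binomial(len(free_positions), config.background_rate)
            chosen = rng.choice(free_positions, size=n_mut, replace=False)
            for p in sorted(int(x) for x in chosen):
                current = base_set(seq[p])
                others = sorted(set("ACGT") - current)
                seq[p] = others[rng.integers(len(others))]
                bg_pos.append(p)
        bg[acc] = bg_pos
        acc_indels: list[tuple[int, str]] = []
        if config.indel_rate > 0 and len(free_positions):
            n_ind = rng.binomial(len(free_positions), config.indel_rate)
            chosen = rng.choice(
                [p for p in free_positions if p not in bg_pos], size=n_ind, replace=False
            )
            for p in sorted((int(x) for x in chosen), reverse=True):
                if rng.integers(2) == 0:
                    seq[p] = ""
                    acc_indels.append((p, "del"))
                else:
                    ins = "ACGT"[rng.integers(4)]
                    seq[p] = seq[p] + ins
                    acc_indels.append((p, f"ins:{ins}"))
        indels[acc] = sorted(acc_indels)
        records.append((acc, left + "".join(seq) + right))

    truth = TruthTable(
        family=config.family,
        reference=reference,
        planted_positions=planted,
        states=states,
        flank_lengths=(len(left), len(right)),
        background_positions=bg,
        indels=indels,
    )
    return records, truth


def with_seed(config: FamilyConfig, seed: int) -> FamilyConfig:
    return replace(config, seed=seed)
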