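"""Detection of single-nucleotide alteration columns and the profile matrix.

An *alteration column* is a reference position where at least one sample's
called base set differs from the reference state's base set.  Missing states
(gap or N) never trigger a column: they assert no call.  The reference
consensus may itself carry ambiguity codes (a heterozygous reference state),
so comparison is set inequality, not mere mismatch; the nominal reference
allele used for zygosity labels is the alphabetically first base of the
reference state's base set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .align import AnchoredMSA
from .iupac import GAP, Zygosity, base_set, classify_state

logger = logging.getLogger(__name__)

_MISSING_CODES = {GAP, "N"}


def reference_base(ref_state: str) -> str:
    """Nominal reference allele of a column: min base of the reference state."""
    return min(base_set(ref_state))


@dataclass(frozen=True)
class AlterationColumn:
    """One detected column: reference state plus every sample's state and zygosity."""

    index: int  # 1-based ordinal among detected columns, by reference position
    reference_position: int  # 0-based on the reference
    reference_state: str
    sample_states: dict[str, tuple[str, Zygosity]] = field(hash=False)

    @property
    def ref_base(self) -> str:
        return reference_base(self.reference_state)


def detect_alteration_columns(msa: AnchoredMSA) -> list[AlterationColumn]:
    """Return the columns of the anchored MSA where any sample deviates.

    A sample deviates when it is covered, asserts a call (not gap/N), and its
    base set differs from the reference state's base set.
    """
    if not msa.rows:
        raise ValueError("MSA has no sample rows")
    columns: list[AlterationColumn] = []
    prev_pos = None
    for p in range(msa.n_columns):
        ref_state = msa.reference[p]
        ref_set = base_set(ref_state)
        altered = False
        for row, mask in zip(msa.rows, msa.coverage):
            c = row[p]
            if not mask[p] or c in _MISSING_CODES:
                continue
            if base_set(c) != ref_set:
                altered = True
                break
        if not altered:
            continue
        rb = reference_base(ref_state)
        states = {}
        for sid, row, mask in zip(msa.sample_ids, msa.rows, msa.coverage):
            c = row[p] if mask[p] else GAP
            states[sid] = (c, classify_state(c, rb))
        if prev_pos is not None and p == prev_pos + 1:
            logger.info("adjacent alteration columns at reference positions %d,%d", prev_pos, p)
        prev_pos = p
        columns.append(
            AlterationColumn(
                index=len(columns) + 1,
                reference_position=p,
                reference_state=ref_state,
                sample_states=states,
            )
        )
    return columns


@dataclass
class ProfileMatrix:
    """Ordered alteration columns x samples, with the reference as a distinguished row."""

    family: str
    reference_id: str
    columns: list[AlterationColumn]
    sample_ids: list[str]

    def __post_init__(self):
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate accession ids: {dupes}")
        for col in self.columns:
            missing = set(self.sample_ids) - set(col.sample_states)
            if missing:
                raise ValueError(f"column {col.index}: no state for {sorted(missing)}")

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def profile(self, sample_id: str) -> tuple[str, ...]:
        """The sample's state codes across alteration columns, in column order."""
        return tuple(col.sample_states[sample_id][0] for col in self.columns)

    def reference_profile(self) -> tuple[str, ...]:
        return tuple(col.reference_state for col in self.columns)

    def to_tsv(self) -> str:
        lines = [f"# family: {self.family}", f"# reference: {self.reference_id}"]
        positions = "\t".join(str(c.reference_position) for c in self.columns)
        lines.append(f"accession\t{positions}")
        lines.append(self.reference_id + "\t" + "\t".join(self.reference_profile()))
        for sid in self.sample_ids:
            lines.append(sid + "\t" + "\t".join(self.profile(sid)))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "ProfileMatrix":
        family = reference_id = None
        body: list[list[str]] = []
        for line in text.splitlines():
            if not line.strip():
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition(":")
                if key.strip() == "family":
                    family = val.strip()
                elif key.strip() == "reference":
                    reference_id = val.strip()
                continue
            body.append(line.split("\t"))
        if family is None or reference_id is None or len(body) < 2:
            raise ValueError("malformed profile TSV")
        positions = [int(x) for x in body[0][1:]]
        rows = {r[0]: r[1:] for r in body[1:]}
        if reference_id not in rows:
            raise ValueError(f"reference row {reference_id!r} missing")
        ref_row = rows.pop(reference_id)
        sample_ids = [r[0] for r in body[1:] if r[0] != reference_id]
        columns = []
        for k, (pos, ref_state) in enumerate(zip(positions, ref_row)):
            rb = reference_base(ref_state)
            states = {sid: (rows[sid][k], classify_state(rows[sid][k], rb)) for sid in sample_ids}
            columns.append(
                AlterationColumn(
                    index=k + 1,
                    reference_position=pos,
                    reference_state=ref_state,
                    sample_states=states,
                )
            )
        return cls(family=family, reference_id=reference_id, columns=columns, sample_ids=sample_ids)

    def to_json(self) -> str:
        """Full zygosity-annotated form."""
        obj = {
            "family": self.family,
            "reference": self.reference_id,
            "columns": [
                {
                    "index": c.index,
                    "reference_position": c.reference_position,
                    "reference_state": c.reference_state,
                    "reference_base": c.ref_base,
                    "samples": {
                        sid: {"state": code, "zygosity": zyg.value}
                        for sid, (code, zyg) in c.sample_states.items()
                    },
                }
                for c in self.columns
            ],
            "samples": self.sample_ids,
        }
        return json.dumps(obj, indent=2)


def build_profile_matrix(
    columns: list[AlterationColumn],
    sample_ids: list[str],
    family: str,
    reference_id: str = "reference",
) -> ProfileMatrix:
    """Assemble the profile matrix; column indices follow reference position order."""
    ordered = sorted(columns, key=lambda c: c.reference_position)
    reindexed = [
        AlterationColumn(
            index=k + 1,
            reference_position=c.reference_position,
            reference_state=c.reference_state,
            sample_states=c.sample_states,
        )
        for k, c in enumerate(ordered)
    ]
    return ProfileMatrix(
        family=family, reference_id=reference_id, columns=reindexed, sample_ids=sample_ids
    )
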