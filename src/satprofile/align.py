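"""Ambiguity-aware pairwise alignment of monomer consensi to a family reference.

Satellite-monomer PCR fragments are near-full-length copies of the reference
monomer, so homology is computed by *free-end-gap* (semi-global) affine-gap
alignment rather than local search: terminal overhangs — primer flanks, ragged
Sanger ends — cost nothing and fall outside the homologous region, while every
internal gap is charged.  Two states count as an identity when their IUPAC base
sets intersect, so a heterozygous consensus call is never penalized against the
reference allele it contains.

Coordinates are 0-based half-open on the reference throughout; 1-based column
numbers appear only in reports.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .iupac import CODE_TO_MASK, GAP, clean_sequence

logger = logging.getLogger(__name__)

_NEG = -1.0e30  # effectively -inf, safe under addition
_EPS = 1e-9


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores. A gap of length k costs ``gap_open + gap_extend*(k-1)``."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5


@dataclass(frozen=True)
class MonomerRecord:
    """One accession's consensus sequence for one satDNA family."""

    accession_id: str
    species: str
    family: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.accession_id}: empty sequence")


def compatible(a: str, b: str) -> bool:
    """True when the two states' base sets intersect (gap never matches)."""
    return (CODE_TO_MASK.get(a.upper(), 0) & CODE_TO_MASK.get(b.upper(), 0)) != 0


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped alignment of one sample against the family reference.

    ``homologous_region`` is the half-open reference interval the identity is
    computed over; initially the reference span covered by the sample, possibly
    narrowed by :func:`trim_homologous_region`.
    """

    sample_id: str
    aligned_sample: str
    aligned_reference: str
    score: float
    homologous_region: tuple[int, int]
    scoring: ScoringScheme = field(default=ScoringScheme(), compare=False)

    def __post_init__(self):
        if len(self.aligned_sample) != len(self.aligned_reference):
            raise ValueError("aligned rows differ in length")

    @property
    def sample_sequence(self) -> str:
        return self.aligned_sample.replace(GAP, "")

    @property
    def reference_sequence(self) -> str:
        return self.aligned_reference.replace(GAP, "")

    def reference_positions(self) -> list[int | None]:
        """Per alignment column: reference position consumed, or None."""
        out: list[int | None] = []
        p = 0
        for c in self.aligned_reference:
            if c == GAP:
                out.append(None)
            else:
                out.append(p)
                p += 1
        return out

    def sample_positions(self) -> list[int | None]:
        out: list[int | None] = []
        p = 0
        for c in self.aligned_sample:
            if c == GAP:
                out.append(None)
            else:
                out.append(p)
                p += 1
        return out

    def region_columns(self) -> range:
        """Alignment-column range covering the homologous region.

        Includes sample-insertion columns strictly inside the region.
        """
        start, end = self.homologous_region
        refpos = self.reference_positions()
        lo = len(refpos)
        hi = 0
        for c, p in enumerate(refpos):
            if p is not None and start <= p < end:
                lo = min(lo, c)
                hi = max(hi, c + 1)
        if lo >= hi:
            return range(0, 0)
        return range(lo, hi)

    @property
    def identity_fraction(self) -> float:
        """Fraction of homologous-region columns whose states are compatible.

        NaN (with a warning) when the region is empty.
        """
        cols = self.region_columns()
        if len(cols) == 0:
            logger.warning("%s: empty homologous region, identity undefined", self.sample_id)
            return math.nan
        n_ok = sum(
            1 for c in cols if compatible(self.aligned_sample[c], self.aligned_reference[c])
        )
        return n_ok / len(cols)


def _mask_array(seq: str) -> np.ndarray:
    return np.array([CODE_TO_MASK[c] for c in seq], dtype=np.int64)


def global_align(
    sample: str,
    reference: str,
    scoring: ScoringScheme = ScoringScheme(),
    sample_id: str = "sample",
) -> PairwiseAlignment:
    """Optimal free-end-gap affine alignment of ``sample`` against ``reference``.

    Gotoh three-state dynamic programme; terminal gaps in either sequence are
    free.  Deterministic: the traceback prefers diagonal over up (gap in
    reference) over left (gap in sample), a gap is closed as early as possible,
    and among tied end cells the one consuming the longest reference prefix on
    the bottom row is taken first.
    """
    a = clean_sequence(sample, sample_id)
    b = clean_sequence(reference, "reference")
    n, m = len(a), len(b)
    sc = scoring
    open_, ext = sc.gap_open, sc.gap_extend

    am = _mask_array(a)
    bm = _mask_array(b)
    sub = np.where((am[:, None] & bm[None, :]) != 0, sc.match, sc.mismatch)

    # M: a[i-1] aligned to b[j-1]; Ix: a[i-1] against a gap (vertical / "up");
    # Iy: gap against b[j-1] (horizontal / "left").  Border cells of M hold 0:
    # alignments may start after a free terminal gap in either sequence.
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)
    Iy = np.full((n + 1, m + 1), _NEG)
    M[0, :] = 0.0
    M[:, 0] = 0.0
    S = np.full((n + 1, m + 1), _NEG)
    S[0, :] = 0.0
    S[:, 0] = 0.0

    jj = np.arange(1, m + 1, dtype=float)
    for i in range(1, n + 1):
        M[i, 1:] = S[i - 1, :m] + sub[i - 1]
        Ix[i, 1:] = np.maximum(M[i - 1, 1:] + open_, Ix[i - 1, 1:] + ext)
        # Iy[i,j] = max_{k<j} M[i,k] + open + ext*(j-1-k), via a running max of
        # u[k] = M[i,k] - ext*k  (horizontal chains only ever start from M).
        u = M[i, :m] - ext * np.arange(m, dtype=float)
        Iy[i, 1:] = open_ + ext * (jj - 1.0) + np.maximum.accumulate(u)
        S[i, 1:] = np.maximum(np.maximum(M[i, 1:], Ix[i, 1:]), Iy[i, 1:])
        S[i, 0] = 0.0

    best = max(float(S[n, :].max()), float(S[:, m].max()))
    end = None
    for j in range(m, -1, -1):
        if S[n, j] >= best - _EPS:
            end = (n, j)
            break
    if end is None or S[end[0], end[1]] < best - _EPS:
        for i in range(n - 1, -1, -1):
            if S[i, m] >= best - _EPS:
                end = (i, m)
                break
    i, j = end

    def pick(i: int, j: int) -> str:
        v = S[i, j]
        if M[i, j] >= v - _EPS:
            return "M"
        if Ix[i, j] >= v - _EPS:
            return "Ix"
        return "Iy"

    cols_a: list[str] = []
    cols_b: list[str] = []
    end_i, end_j = i, j
    state = pick(i, j) if i > 0 and j > 0 else "M"
    while i > 0 and j > 0:
        if state == "M":
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            i, j = i - 1, j - 1
            if i == 0 or j == 0:
                break
            state = pick(i, j)
        elif state == "Ix":
            cols_a.append(a[i - 1])
            cols_b.append(GAP)
            state = "M" if M[i - 1, j] + open_ >= Ix[i, j] - _EPS else "Ix"
            i -= 1
        else:  # Iy
            cols_a.append(GAP)
            cols_b.append(b[j - 1])
            state = "M" if M[i, j - 1] + open_ >= Iy[i, j] - _EPS else "Iy"
            j -= 1

    core_a = "".join(reversed(cols_a))
    core_b = "".join(reversed(cols_b))
    lead_a = a[:i] + GAP * j
    lead_b = GAP * i + b[:j]
    tail_a = a[end_i:] + GAP * (m - end_j)
    tail_b = GAP * (n - end_i) + b[end_j:]
    aligned_a = lead_a + core_a + tail_a
    aligned_b = lead_b + core_b + tail_b

    region = (j, end_j) if end_j > j else (0, 0)
    aln = PairwiseAlignment(
        sample_id=sample_id,
        aligned_sample=aligned_a,
        aligned_reference=aligned_b,
        score=best,
        homologous_region=region,
        scoring=sc,
    )
    assert aln.sample_sequence == a and aln.reference_sequence == b
    return aln


def alignment_score(aligned_a: str, aligned_b: str, scoring: ScoringScheme = ScoringScheme()) -> float:
    """Score an explicit gapped alignment under the free-end-gap convention.

    Independent of the DP: walks the columns, charging each maximal gap run
    ``gap_open + gap_extend*(len-1)`` unless it touches either end of the
    alignment.  Used for self-checks and by the test suite's oracle.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("rows differ in length")
    ncol = len(aligned_a)
    score = 0.0
    run_row = None  # which row the current gap run is in
    run_len = 0
    run_start = 0

    def charge(start: int, length: int) -> float:
        if start == 0 or start + length == ncol:
            return 0.0
        return scoring.gap_open + scoring.gap_extend * (length - 1)

    for c in range(ncol):
        ca, cb = aligned_a[c], aligned_b[c]
        if ca == GAP and cb == GAP:
            raise ValueError("column with gaps in both rows")
        row = 0 if ca == GAP else (1 if cb == GAP else None)
        if row is None:
            if run_len:
                score += charge(run_start, run_len)
                run_len = 0
            score += scoring.match if compatible(ca, cb) else scoring.mismatch
            run_row = None
        else:
            if run_len and row != run_row:
                score += charge(run_start, run_len)
                run_len = 0
            if run_len == 0:
                run_start, run_row = c, row
            run_len += 1
    if run_len:
        score += charge(run_start, run_len)
    return score


def percent_homology(aln: PairwiseAlignment) -> int | None:
    """Identity over the homologous region as a whole percent (round half up).

    Matches the integer-percent granularity homology is conventionally
    reported at.  None (with a warning) for an empty region.
    """
    f = aln.identity_fraction
    if math.isnan(f):
        return None
    return int(math.floor(100.0 * f + 0.5))


def trim_homologous_region(
    aln: PairwiseAlignment,
    min_flank_identity: float = 0.5,
    window: int = 10,
    flank_lengths: tuple[int, int] | None = None,
) -> PairwiseAlignment:
    """Narrow the homologous region to exclude primer flanks and ragged ends.

    With ``flank_lengths=(left, right)`` (sample coordinates) the columns
    consuming those sample bases are excluded exactly.  Otherwise columns are
    dropped from either end while the terminal ``window`` columns of the region
    have identity below ``min_flank_identity``.
    """
    refpos = aln.reference_positions()
    cols = list(aln.region_columns())
    if not cols:
        raise ValueError(f"{aln.sample_id}: homologous region is empty")

    if flank_lengths is not None:
        left, right = flank_lengths
        spos = aln.sample_positions()
        n_sample = len(aln.sample_sequence)
        keep = [
            c
            for c in cols
            if spos[c] is None or (left <= spos[c] < n_sample - right)
        ]
        if left or right:
            logger.info(
                "%s: trimmed flanks of %d/%d bp from the homologous region",
                aln.sample_id,
                left,
                right,
            )
        cols = keep
    else:
        def window_identity(cs: list[int]) -> float:
            w = cs[:window]
            return sum(
                1 for c in w if compatible(aln.aligned_sample[c], aln.aligned_reference[c])
            ) / len(w)

        while cols and window_identity(cols) < min_flank_identity:
            cols = cols[1:]
        while cols and window_identity(cols[::-1]) < min_flank_identity:
            cols = cols[:-1]

    ref_in = [refpos[c] for c in cols if refpos[c] is not None]
    if not ref_in:
        raise ValueError(f"{aln.sample_id}: homologous region collapsed to empty after trimming")
    region = (min(ref_in), max(ref_in) + 1)
    if region != aln.homologous_region:
        logger.info(
            "%s: homologous region trimmed %s -> %s",
            aln.sample_id,
            aln.homologous_region,
            region,
        )
    return replace(aln, homologous_region=region)


@dataclass
class AnchoredMSA:
    """Sample rows projected onto reference coordinates.

    Every row has the reference's length; a cell holds the sample state placed
    against that reference position, '-' where the sample has a deletion, and
    '-' with ``coverage`` False where the position lies outside the sample's
    homologous region.  Sample insertions relative to the reference are dropped
    (and counted): alteration columns are positions *of the reference*.
    """

    reference_id: str
    reference: str
    sample_ids: list[str]
    rows: list[str]
    coverage: list[np.ndarray]
    dropped_insertions: dict[str, int]

    @property
    def n_columns(self) -> int:
        return len(self.reference)

    def to_fasta(self) -> str:
        parts = [f">{self.reference_id}\n{self.reference}\n"]
        for sid, row in zip(self.sample_ids, self.rows):
            parts.append(f">{sid}\n{row}\n")
        return "".join(parts)


def build_anchored_msa(
    alignments: list[PairwiseAlignment],
    reference: str,
    reference_id: str = "reference",
) -> AnchoredMSA:
    """Project pairwise alignments sharing one reference into a reference-anchored MSA."""
    ref = clean_sequence(reference, reference_id)
    sample_ids, rows, cov = [], [], []
    dropped: dict[str, int] = {}
    seen: set[str] = set()
    for aln in alignments:
        if aln.reference_sequence != ref:
            raise ValueError(f"{aln.sample_id}: aligned to a different reference")
        if aln.sample_id in seen:
            raise ValueError(f"duplicate sample id {aln.sample_id!r}")
        seen.add(aln.sample_id)
        row = [GAP] * len(ref)
        mask = np.zeros(len(ref), dtype=bool)
        start, end = aln.homologous_region
        refpos = aln.reference_positions()
        n_ins = 0
        region = set(aln.region_columns())
        for c, p in enumerate(refpos):
            if p is None:
                if c in region and aln.aligned_sample[c] != GAP:
                    n_ins += 1
                continue
            if start <= p < end:
                row[p] = aln.aligned_sample[c]
                mask[p] = True
        if n_ins:
            logger.info("%s: dropped %d sample-insertion column(s)", aln.sample_id, n_ins)
        dropped[aln.sample_id] = n_ins
        sample_ids.append(aln.sample_id)
        rows.append("".join(row))
        cov.append(mask)
    return AnchoredMSA(
        reference_id=reference_id,
        reference=ref,
        sample_ids=sample_ids,
        rows=rows,
        coverage=cov,
        dropped_insertions=dropped,
    )
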