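"""Shared fixtures and the independent brute-force alignment oracle."""

from __future__ import annotations

import itertools

import pytest

from satprofile.align import ScoringScheme, build_anchored_msa, global_align, trim_homologous_region
from satprofile.fixtures import con2_fixture
from satprofile.profiling import build_profile_matrix, detect_alteration_columns
from satprofile.synthetic import generate_dataset

# Independent IUPAC table for the oracle (deliberately not imported from the package).
ORACLE_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


def enumerate_alignments(n: int, m: int):
    """Yield every gapped alignment of an n-mer vs an m-mer as a move string.

    Moves: 'D' consume both, 'U' consume first sequence only (gap in second),
    'L' consume second only.  Pure enumeration; no dynamic programming.
    """
    def rec(i, j, moves):
        if i == n and j == m:
            yield moves
            return
        if i < n and j < m:
            yield from rec(i + 1, j + 1, moves + "D")
        if i < n:
            yield from rec(i + 1, j, moves + "U")
        if j < m:
            yield from rec(i, j + 1, moves + "L")

    yield from rec(0, 0, "")


def score_moves(moves: str, a: str, b: str, sc: ScoringScheme) -> float:
    """Score one enumerated alignment under the free-end-gap affine convention.

    A maximal gap run costs ``gap_open + gap_extend*(len-1)`` unless it touches
    the first or last alignment column; aligned columns score match when the
    IUPAC base sets intersect.
    """
    score = 0.0
    i = j = 0
    runs = [(kind, len(list(g))) for kind, g in itertools.groupby(moves)]
    col = 0
    ncol = len(moves)
    for kind, length in runs:
        if kind == "D":
            for _ in range(length):
                hit = ORACLE_SETS[a[i]] & ORACLE_SETS[b[j]]
                score += sc.match if hit else sc.mismatch
                i += 1
                j += 1
        else:
            if kind == "U":
                i += length
            else:
                j += length
            terminal = col == 0 or col + length == ncol
            if not terminal:
                score += sc.gap_open + sc.gap_extend * (length - 1)
        col += length
    return score


def brute_force_best_score(a: str, b: str, sc: ScoringScheme = ScoringScheme()) -> float:
    return max(score_moves(m, a, b, sc) for m in enumerate_alignments(len(a), len(b)))


def run_family(config, reference_id=None, trim=True, flank_lengths=None):
    """Generator -> alignment -> trimming -> MSA -> profile matrix, in one step."""
    records, truth = generate_dataset(config)
    ref_id = reference_id or f"{config.family}_reference"
    alignments = []
    for acc, seq in records:
        aln = global_align(seq, truth.reference, sample_id=acc)
        if trim:
            aln = trim_homologous_region(aln, flank_lengths=flank_lengths)
        alignments.append(aln)
    msa = build_anchored_msa(alignments, truth.reference, reference_id=ref_id)
    columns = detect_alteration_columns(msa)
    matrix = build_profile_matrix(columns, msa.sample_ids, family=config.family, reference_id=ref_id)
    return records, truth, msa, matrix


@pytest.fixture(scope="session")
def con2_run():
    """Noise-free CON2 fixture dataset run through the full analysis once."""
    return run_family(con2_fixture(seed=11))


CON2_GROUP1 = [
    "D. antarctica KEW-0522816",
    "D. antarctica KEW-0661919",
    "D. antarctica KEW-0521613",
    "D. parvula",
]
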