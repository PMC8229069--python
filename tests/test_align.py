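"""Pairwise alignment, homology percentages, trimming, and the anchored MSA."""

import dataclasses
import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from satprofile.align import (
    ScoringScheme,
    alignment_score,
    build_anchored_msa,
    compatible,
    global_align,
    percent_homology,
    trim_homologous_region,
)
from satprofile.fixtures import con2_fixture
from satprofile.synthetic import default_flanks, generate_dataset

from conftest import brute_force_best_score, run_family

SEQS = st.text(alphabet="ACGT", min_size=1, max_size=30)


def test_identity_alignment():
    aln = global_align("ACGTACGTAC", "ACGTACGTAC")
    assert aln.identity_fraction == 1.0
    assert "-" not in aln.aligned_sample + aln.aligned_reference
    assert percent_homology(aln) == 100


def test_single_substitution_identity():
    aln = global_align("ACGTACGTAC", "ACGAACGTAC")
    assert aln.identity_fraction == pytest.approx(0.9)


def test_ambiguity_codes_count_as_identity():
    """A heterozygous call is compatible with the reference allele it contains."""
    aln = global_align("ARGT", "AAGT")
    assert aln.identity_fraction == 1.0
    assert compatible("R", "A") and not compatible("R", "C")
    assert not compatible("-", "A")


def test_dp_score_matches_brute_force_enumeration():
    """DP optimum equals exhaustive enumeration over all gapped alignments
    for a fixed random sample of short sequence pairs."""
    rng = random.Random(20240517)
    lengths = [(2, 3), (3, 3), (4, 4), (4, 6), (5, 5), (6, 6)]
    for n, m in lengths:
        a = "".join(rng.choice("ACGT") for _ in range(n))
        b = "".join(rng.choice("ACGT") for _ in range(m))
        aln = global_align(a, b)
        assert aln.score == pytest.approx(brute_force_best_score(a, b)), (a, b)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(a=SEQS, b=SEQS)
def test_score_symmetry_and_input_recovery(a, b):
    """Aligning (a,b) and (b,a) gives the same score; degapping the rows
    recovers the inputs; the emitted alignment rescores to the reported score."""
    f = global_align(a, b)
    r = global_align(b, a)
    assert f.score == pytest.approx(r.score)
    assert f.sample_sequence == a and f.reference_sequence == b
    assert alignment_score(f.aligned_sample, f.aligned_reference) == pytest.approx(f.score)


def test_identity_fraction_one_iff_identical_over_region():
    aln = global_align("ACGTAC", "ACGTAC")
    assert aln.identity_fraction == 1.0
    aln2 = global_align("ACGTAC", "ACCTAC")
    assert aln2.identity_fraction < 1.0


def test_percent_homology_rounds_to_integer():
    ref = ("ACGT" * 135)[:538]
    sample = list(ref)
    for p in (10, 110, 210, 310, 410):  # 5 substitutions in 538 -> 533/538 -> 99%
        sample[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[sample[p]]
    aln = global_align("".join(sample), ref)
    assert aln.identity_fraction == pytest.approx(533 / 538)
    assert percent_homology(aln) == 99


def test_percent_homology_recount_on_planted_noise():
    """Reported percent equals an independent recount of matching columns."""
    rng = random.Random(7)
    ref = "".join(rng.choice("ACGT") for _ in range(333))
    sample = list(ref)
    for p in rng.sample(range(333), int(0.07 * 333)):
        sample[p] = rng.choice(sorted(set("ACGT") - {sample[p]}))
    aln = global_align("".join(sample), ref)
    cols = aln.region_columns()
    n_match = sum(
        1 for c in cols if compatible(aln.aligned_sample[c], aln.aligned_reference[c])
    )
    assert percent_homology(aln) == int(math.floor(100 * n_match / len(cols) + 0.5))


def test_trim_noop_on_clean_alignment():
    aln = global_align("ACGTACGTACGTACGT", "ACGTACGTACGTACGT")
    assert trim_homologous_region(aln).homologous_region == aln.homologous_region


def test_reference_self_alignment_full_region():
    ref = "ACGTTGCAACGTTGCA"
    aln = global_align(ref, ref)
    assert trim_homologous_region(aln).homologous_region == (0, len(ref))


def test_flanked_sample_region_excludes_flanks():
    """Non-homologous primer flanks fall outside the homologous region on
    noise-free synthetic input (generator truth table gives the flank lengths)."""
    left, right = default_flanks()
    cfg = dataclasses.replace(con2_fixture(seed=2), left_flank=left, right_flank=right)
    records, truth = generate_dataset(cfg)
    acc, seq = records[0]
    assert len(seq) == 538 + truth.flank_lengths[0] + truth.flank_lengths[1]
    aln = global_align(seq, truth.reference, sample_id=acc)
    aln = trim_homologous_region(aln, flank_lengths=truth.flank_lengths)
    assert aln.homologous_region == (0, 538)
    assert percent_homology(aln) == 100


def test_trim_collapse_names_sample():
    aln = global_align("TTTT", "CCCC", sample_id="badsample")
    with pytest.raises(ValueError, match="badsample"):
        trim_homologous_region(aln, min_flank_identity=1.1, window=2)


def test_msa_identical_sample():
    ref = "ACGTACGTAC"
    msa = build_anchored_msa([global_align(ref, ref, sample_id="s1")], ref)
    assert msa.rows == [ref]
    assert msa.n_columns == len(ref)


def test_msa_dimensions_con2(con2_run):
    """13 noise-free CON2 consensi anchor into a 13x538 matrix (plus reference)."""
    _, _, msa, _ = con2_run
    assert len(msa.rows) == 13
    assert msa.n_columns == 538
    assert all(len(r) == 538 for r in msa.rows)
    assert msa.to_fasta().count(">") == 14


def test_msa_deletion_marked_missing():
    ref = "ACGTACGTACGTACGTACGT"
    sample = ref[:8] + ref[9:]  # delete reference position 8
    aln = global_align(sample, ref, sample_id="del1")
    msa = build_anchored_msa([aln], ref)
    assert msa.rows[0][8] == "-"
    assert msa.rows[0][:8] == ref[:8] and msa.rows[0][9:] == ref[9:]


def test_msa_insertion_dropped_and_counted():
    ref = "ACGTACGTACGTACGTACGT"
    sample = ref[:10] + "T" + ref[10:]
    aln = global_align(sample, ref, sample_id="ins1")
    msa = build_anchored_msa([aln], ref)
    assert msa.rows[0] == ref
    assert msa.dropped_insertions["ins1"] == 1


def test_msa_rejects_foreign_reference():
    aln = global_align("ACGTAC", "ACGTAC", sample_id="s")
    with pytest.raises(ValueError, match="different reference"):
        build_anchored_msa([aln], "ACGTAA")


def test_noise_free_rows_equal_reference_except_planted(con2_run):
    """Substitution-only profiles: each MSA row deviates from the reference
    exactly at that accession's planted columns."""
    records, truth, msa, _ = con2_run
    for acc, row in zip(msa.sample_ids, msa.rows):
        diffs = {p for p in range(msa.n_columns) if row[p] != msa.reference[p]}
        planted_diffs = {
            p for p, code in truth.states[acc].items() if code != truth.reference[p]
        }
        assert diffs == planted_diffs


def test_custom_scoring_respected():
    heavy = ScoringScheme(match=1.0, mismatch=-3.0, gap_open=-1.0, gap_extend=-0.5)
    aln = global_align("ACGT", "AGT", scoring=heavy)
    assert aln.scoring == heavy


def test_invalid_characters_rejected_before_alignment():
    with pytest.raises(ValueError, match="position 2"):
        global_align("AXGT", "ACGT")
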