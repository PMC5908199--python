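"""p-distance divergence and diversity on aligned nucleotide sequences."""

from itertools import combinations

import numpy as np
import pytest

from fcserology import (
    AlignedSequenceSet,
    DegenerateInputError,
    InputError,
    divergence_report,
    diversity_report,
    mean_pairwise_distance,
    percent_divergence,
)
from fcserology.errors import ConfigurationError
from fcserology.synthetic import (
    SyntheticSequenceConfig,
    generate_sequences,
    random_reference,
)


def brute_force_mean_pairwise(seqs):
    """Oracle: double loop over pairs, counting gap/N-free differing sites."""
    dists = []
    for a, b in combinations(seqs, 2):
        comp = diff = 0
        for x, y in zip(a, b):
            if x in "N-" or y in "N-":
                continue
            comp += 1
            diff += x != y
        dists.append(diff / comp)
    return sum(dists) / len(dists)


def test_percent_divergence_hand_examples():
    assert percent_divergence("ACGT", "ACGT").percent_difference == 0.0
    r = percent_divergence("AAAAAAAATT", "AAAAAAAAAA")
    assert (r.compared_sites, r.differing_sites) == (10, 2)
    assert r.percent_difference == pytest.approx(20.0)
    # gap column excluded: 1 difference over 4 comparable sites
    r = percent_divergence("AC-GT", "ACAGA")
    assert (r.compared_sites, r.differing_sites) == (4, 1)
    assert r.percent_difference == pytest.approx(25.0)


def test_percent_divergence_symmetric_and_guards():
    a, b = "ACGTN-", "AC-TNA"
    r1, r2 = percent_divergence(a, b), percent_divergence(b, a)
    assert r1.percent_difference == r2.percent_difference
    with pytest.raises(InputError):
        percent_divergence("ACG", "ACGT")
    with pytest.raises(DegenerateInputError):
        percent_divergence("---", "AAA")
    with pytest.raises(InputError):
        percent_divergence("AXG", "ACG")


def test_pairwise_distance_matches_ape_reference():
    """Frozen reference: ape::dist.dna(model='raw', pairwise.deletion=TRUE)
    on the same four sequences."""
    seqs = {"s1": "ACGTACGTAC", "s2": "ACGTACGTAT",
            "s3": "AC-TACGAAC", "s4": "NCGTACGTAC"}
    expected = {("s1", "s2"): 0.1, ("s1", "s3"): 0.1111111111,
                ("s1", "s4"): 0.0, ("s2", "s3"): 0.2222222222,
                ("s2", "s4"): 0.1111111111, ("s3", "s4"): 0.125}
    for (i, j), want in expected.items():
        got = percent_divergence(seqs[i], seqs[j]).p_distance
        assert got == pytest.approx(want, abs=1e-9), (i, j)


def test_mean_pairwise_distance_hand_and_identical():
    idid = AlignedSequenceSet(["a", "b", "c"], ["ACGT" * 3] * 3)
    assert mean_pairwise_distance(idid) == 0.0
    # pairwise differences 1, 2, 3 over length 10 -> mean 0.2
    s = AlignedSequenceSet(
        ["a", "b", "c"],
        ["AAAAAAAAAA", "CAAAAAAAAA", "CCCAAAAAAA"])
    assert mean_pairwise_distance(s) == pytest.approx((0.1 + 0.2 + 0.3) / 3)


def test_mean_pairwise_matches_brute_force_oracle(rng):
    for n in (3, 5, 8, 12):
        seqs = ["".join(rng.choice(list("ACGT-N"), size=40,
                                   p=[0.23, 0.23, 0.23, 0.23, 0.05, 0.03]))
                for _ in range(n)]
        s = AlignedSequenceSet([f"id{i}" for i in range(n)], seqs)
        assert mean_pairwise_distance(s) == pytest.approx(
            brute_force_mean_pairwise([x.upper() for x in seqs]))


def test_mean_pairwise_invariant_under_reordering(rng):
    seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(6)]
    ids = [f"id{i}" for i in range(6)]
    base = mean_pairwise_distance(AlignedSequenceSet(ids, seqs))
    order = rng.permutation(6)
    shuf = mean_pairwise_distance(AlignedSequenceSet(
        [ids[i] for i in order], [seqs[i] for i in order]))
    assert base == pytest.approx(shuf)


def test_complete_deletion_drops_any_gap_column():
    s = AlignedSequenceSet(["a", "b", "c"],
                           ["ACGTA", "AC-TA", "TCGTA"])
    # complete deletion removes column 3: remaining ACTA/ACTA/TCTA
    assert mean_pairwise_distance(s, deletion="complete") == pytest.approx(
        (1 / 4 + 0 + 1 / 4) / 3)
    with pytest.raises(InputError):
        mean_pairwise_distance(s, deletion="nope")


def test_divergence_report_shape_and_values():
    ref = "ACGTACGTAC"
    sets = {
        "subj1": AlignedSequenceSet(["subj1|6|1"], [ref]),
        "subj2": AlignedSequenceSet(["subj2|6|1", "subj2|6|2"],
                                    ["ACGTACGTAT", "ACGTACGAAC"]),
    }
    rep = divergence_report(sets, {"ConC": ref})
    assert len(rep) == 2  # subjects x references
    assert rep.set_index("subject").loc["subj1", "mean_percent_divergence"] == 0.0
    assert rep.set_index("subject").loc["subj2", "mean_percent_divergence"] == (
        pytest.approx(10.0))
    with pytest.raises(ConfigurationError):
        divergence_report(sets, {"bad": "ACGT"})
    with pytest.raises(ConfigurationError):
        divergence_report(sets, {})


def test_generator_divergence_consistent_with_substitution_rate():
    """Sequences simulated at per-site rate r diverge from the reference
    by 100r% within 3 Monte-Carlo standard errors."""
    r, length, n = 0.05, 1000, 50
    ref = random_reference(length, seed=3)
    cfg = SyntheticSequenceConfig(reference_length=length, n_sequences=n,
                                  per_site_substitution_prob=r, seed=11)
    seqs = generate_sequences(cfg, ref)
    rep = divergence_report({"sim": seqs}, {"ref": ref})
    mean_div = rep["mean_percent_divergence"].iloc[0]
    se = 100.0 * np.sqrt(r * (1 - r) / length / n)
    assert abs(mean_div - 100.0 * r) < 3 * se


def test_diversity_report_groups_by_subject_and_timepoint():
    s = AlignedSequenceSet(
        ["p1|6|1", "p1|6|2", "p1|12|1", "p2|6|1"],
        ["ACGT", "ACGA", "ACGT", "TTTT"])
    rep = diversity_report(s)
    # only p1 at month 6 has >= 2 sequences
    assert len(rep) == 1
    row = rep.iloc[0]
    assert (row["subject"], row["timepoint"]) == ("p1", "6")
    assert row["mean_pairwise_distance_pct"] == pytest.approx(25.0)


def test_fasta_roundtrip(tmp_path, rng):
    seqs = ["".join(rng.choice(list("ACGT"), size=20)) for _ in range(4)]
    ids = [f"subj{i}|6|{i}" for i in range(4)]
    s = AlignedSequenceSet(ids, seqs)
    path = tmp_path / "aln.fasta"
    s.to_fasta(path)
    back = AlignedSequenceSet.from_fasta(path)
    assert back.ids == ids and back.sequences == seqs
    assert back.subject_of(ids[2]) == "subj2"
    assert back.timepoint_of(ids[2]) == "6"
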