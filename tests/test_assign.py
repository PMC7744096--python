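"""Preprocessing, 3'-anchored alignment and the multimapping policy."""

import numpy as np
import pytest

from chargeseq import (
    ChargeProfile,
    LibraryParams,
    OXIDIZED,
    align_read,
    assign_and_count,
    preprocess_read_pair,
    process_library,
    simulate_read_library,
)
from chargeseq.assign import (
    MULTI_ACROSS,
    MULTI_WITHIN,
    SPIKE_IN,
    UNASSIGNED,
    UNIQUE_GENE,
    ProcessedRead,
)
from chargeseq.chemistry import ADAPTOR_3P, ADAPTOR_RT
from chargeseq.reference import reverse_complement

Q40 = chr(33 + 40)
Q2 = chr(33 + 2)


def _pair_from_insert(insert, read_length=75):
    r1 = (insert + ADAPTOR_3P)[:read_length]
    r2 = (reverse_complement(insert) + ADAPTOR_RT)[:read_length]
    return (r1, Q40 * len(r1)), (r2, Q40 * len(r2))


class TestPreprocess:
    def test_full_adaptor_trimmed_at_start(self):
        insert = "ACGTAC" * 8  # 48 nt
        mate1 = insert + ADAPTOR_3P
        read, reason = preprocess_read_pair(
            "r1", (mate1, Q40 * len(mate1)), ("A" * 10, Q40 * 10)
        )
        assert reason is None
        assert read.sequence == insert

    def test_one_mismatch_adaptor_trimmed(self):
        insert = "ACGTAC" * 8
        adaptor_mut = "T" + ADAPTOR_3P[1:]
        mate1 = insert + adaptor_mut
        read, _ = preprocess_read_pair(
            "r1", (mate1, Q40 * len(mate1)), ("A" * 10, Q40 * 10)
        )
        assert read.sequence == insert

    def test_too_short_discarded(self):
        mate1 = "ACGTACGTAC" + ADAPTOR_3P  # 10 nt insert
        read, reason = preprocess_read_pair(
            "r1", (mate1, Q40 * len(mate1)), ("A" * 10, Q40 * 10)
        )
        assert read is None and reason == "too_short"

    def test_non_overlapping_mates_fall_back_to_mate1(self):
        rng = np.random.default_rng(0)
        insert = "".join("ACGT"[i] for i in rng.integers(0, 4, size=200))
        (s1, q1), (s2, q2) = _pair_from_insert(insert, read_length=75)
        read, _ = preprocess_read_pair("r1", (s1, q1), (s2, q2))
        assert read.source == "mate1_only"
        assert read.sequence == insert[:75]

    def test_merge_recovers_full_insert(self):
        rng = np.random.default_rng(1)
        for length in (63, 68, 74, 75, 80, 93):
            insert = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
            (s1, q1), (s2, q2) = _pair_from_insert(insert)
            read, _ = preprocess_read_pair("r", (s1, q1), (s2, q2))
            assert read.source == "merged"
            assert read.sequence == insert, f"length {length}"

    def test_disagreement_resolved_toward_higher_quality(self):
        # fully overlapping 40-nt mates differing at one position
        insert = "ACGT" * 10
        pos = 17
        variant = insert[:pos] + "G" + insert[pos + 1:]
        assert variant != insert
        q1 = Q40 * pos + Q2 + Q40 * (len(insert) - pos - 1)  # low quality at pos
        s2 = reverse_complement(insert)
        read, _ = preprocess_read_pair("r", (variant, q1), (s2, Q40 * len(s2)))
        assert read.sequence == insert  # the quality-40 call wins

        # symmetric: mate 1 carries the high-quality call
        read2, _ = preprocess_read_pair(
            "r", (variant, Q40 * len(variant)),
            (s2, (Q2 * len(s2))),
        )
        assert read2.sequence == variant

    def test_merge_agrees_with_exhaustive_enumeration(self):
        """Chosen overlap matches a brute-force scan of merge positions."""
        rng = np.random.default_rng(2)
        insert = "".join("ACGT"[i] for i in rng.integers(0, 4, size=40))
        s1 = insert[:30]
        s2 = reverse_complement(insert[10:])
        read, _ = preprocess_read_pair("r", (s1, Q40 * 30), (s2, Q40 * 30))
        # brute force: the only shift placing >=15 matching bases is offset 10
        best = None
        for t in range(-29, 30):
            a = s1[max(t, 0):]
            b = reverse_complement(s2)[max(-t, 0):]
            o = min(len(a), len(b))
            if o < 15:
                continue
            mm = sum(x != y for x, y in zip(a[:o], b[:o]))
            if mm <= 2 and (best is None or o > best[0]):
                best = (o, t)
        assert best == (20, 10)
        assert read.source == "merged"
        assert read.sequence == insert


def _oracle_hits(seq, ref, max_mm=1):
    """Exhaustive 3'-anchored Hamming scan over every mature sequence."""
    out = []
    mats = [(m, tuple(sorted(g))) for m, g in ref.mature_sequences.items()]
    mats.append((ref.spike_mature, (ref.spike_in.gene_id,)))
    for mat, gene_ids in mats:
        n = min(len(seq), len(mat))
        if n < 20:
            continue
        mm = 0
        for a, b in zip(seq[-n:], mat[-n:]):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        if mm <= max_mm:
            for g in gene_ids:
                out.append((g, mm, n))
    out.sort(key=lambda h: (h[1], -h[2], h[0]))
    return out


class TestAlign:
    def test_identity_full_overlap(self, six_gene_index):
        mat = six_gene_index.gene_to_mature["mm-Gln-TTG-1-1"]
        hits = align_read(mat, six_gene_index)
        assert hits[0].gene_id == "mm-Gln-TTG-1-1"
        assert hits[0].mismatches == 0
        assert hits[0].aligned_length == len(mat)

    def test_single_substitution_retained(self, six_gene_index):
        mat = six_gene_index.gene_to_mature["mm-Val-AAC-1-1"]
        read = mat[:40] + ("A" if mat[40] != "A" else "C") + mat[41:]
        hits = align_read(read, six_gene_index)
        best = [h for h in hits if h.gene_id == "mm-Val-AAC-1-1"]
        assert best and best[0].mismatches == 1

    def test_two_substitutions_rejected(self, six_gene_index):
        mat = six_gene_index.gene_to_mature["mm-Val-AAC-1-1"]
        read = list(mat)
        for pos in (30, 50):
            read[pos] = "A" if mat[pos] != "A" else "C"
        hits = align_read("".join(read), six_gene_index)
        assert all(h.gene_id != "mm-Val-AAC-1-1" for h in hits)

    def test_5prime_truncation_allowed(self, six_gene_index):
        mat = six_gene_index.gene_to_mature["mm-iMet-CAT-1-1"]
        hits = align_read(mat[-30:], six_gene_index)
        assert hits[0].gene_id == "mm-iMet-CAT-1-1"
        assert hits[0].aligned_length == 30

    def test_n_counts_as_mismatch(self, six_gene_index):
        mat = six_gene_index.gene_to_mature["mm-Val-AAC-1-1"]
        read = mat[:30] + "NN" + mat[32:]
        hits = align_read(read, six_gene_index)
        assert all(h.gene_id != "mm-Val-AAC-1-1" for h in hits)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_exhaustive_oracle(self, six_gene_index, seed):
        rng = np.random.default_rng(seed)
        mats = sorted(six_gene_index.mature_sequences) + [six_gene_index.spike_mature]
        for _ in range(400):
            kind = rng.integers(0, 3)
            if kind == 0:  # random sequence
                read = "".join("ACGT"[i] for i in rng.integers(0, 4, size=60))
            else:
                mat = mats[rng.integers(0, len(mats))]
                start = rng.integers(0, len(mat) - 20 + 1)
                read = list(mat[start:])
                for _ in range(rng.integers(0, 3)):
                    p = rng.integers(0, len(read))
                    read[p] = "ACGT"[rng.integers(0, 4)]
                read = "".join(read)
            got = [(h.gene_id, h.mismatches, h.aligned_length)
                   for h in align_read(read, six_gene_index)]
            expected = _oracle_hits(read, six_gene_index)
            assert sorted(got) == sorted(expected)
            if expected:
                assert (got[0][1], -got[0][2]) == (expected[0][1], -expected[0][2])


class TestAssign:
    def test_identical_gene_copies_count_within_isodecoder(self, six_gene_index):
        mat = six_gene_index.gene_to_mature["mm-Gln-CTG-1-1"]
        reads = [ProcessedRead("r0", mat, "merged")]
        assignments, counts = assign_and_count(reads, six_gene_index)
        assert assignments[0].status == MULTI_WITHIN
        assert assignments[0].isodecoder == "Gln-CTG"
        assert counts.isodecoder_counts["Gln-CTG"] == 1

    def test_strictly_better_hit_wins(self, six_gene_index):
        # the 1-substitution Gln-CTG variant gene: perfect hit there,
        # 1-mismatch hit on the other copies -> unique assignment
        mat = six_gene_index.gene_to_mature["mm-Gln-CTG-3-1"]
        assignments, _ = assign_and_count(
            [ProcessedRead("r0", mat, "merged")], six_gene_index
        )
        assert assignments[0].status == UNIQUE_GENE
        assert assignments[0].gene_hits[0].gene_id == "mm-Gln-CTG-3-1"

    def test_spike_reads_never_count_toward_isodecoders(self, six_gene_index):
        assignments, counts = assign_and_count(
            [ProcessedRead("r0", six_gene_index.spike_mature, "merged")],
            six_gene_index,
        )
        assert assignments[0].status == SPIKE_IN
        assert counts.spike_in == 1
        assert sum(counts.isodecoder_counts.values()) == 0

    def test_no_hit_and_discarded_reads_are_unassigned(self, six_gene_index):
        junk = "ACGT" * 15
        _, counts = assign_and_count(
            [ProcessedRead("r0", junk, "merged"), None], six_gene_index
        )
        assert counts.unassigned == 2
        assert counts.library_size == 2

    def test_empty_read_set(self, six_gene_index):
        _, counts = assign_and_count([], six_gene_index)
        assert counts.library_size == 0
        counts.check_conservation()

    def test_cross_isodecoder_tie_is_ambiguous(self):
        from chargeseq import TrnaGene, build_reference

        # two isodecoders sharing their entire 3' half: a 3'-half read ties
        rng = np.random.default_rng(9)
        shared = "".join("ACGT"[i] for i in rng.integers(0, 4, size=36))
        a5 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=36))
        b5 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=36))
        genes = [
            TrnaGene("gA", "Gln", "CTG", a5 + shared),
            TrnaGene("gB", "Gln", "TTG", b5 + shared),
        ]
        spike = TrnaGene(
            "sp", "Phe", "GAA",
            "".join("ACGT"[i] for i in rng.integers(0, 4, size=76)),
            is_spike_in=True,
        )
        ref = build_reference(genes, spike)
        read = shared + "CCA"
        assignments, counts = assign_and_count(
            [ProcessedRead("r0", read, "merged")], ref
        )
        assert assignments[0].status == MULTI_ACROSS
        assert counts.ambiguous == 1
        assert sum(counts.isodecoder_counts.values()) == 0

    def test_misincorporation_robustness(self, sim_index):
        """One substitution at a modified position keeps the assignment."""
        from chargeseq import default_modified_positions

        modified = default_modified_positions(sim_index)
        checked = 0
        for gene_id, positions in sorted(modified.items()):
            if not positions:
                continue
            mat = sim_index.gene_to_mature[gene_id]
            true_key = sim_index.isodecoder_of(gene_id)
            pos = positions[0]
            mutated = mat[:pos] + ("C" if mat[pos] != "C" else "G") + mat[pos + 1:]
            a_clean, _ = assign_and_count(
                [ProcessedRead("r", mat, "merged")], sim_index
            )
            a_mut, _ = assign_and_count(
                [ProcessedRead("r", mutated, "merged")], sim_index
            )
            assert a_clean[0].isodecoder == true_key
            assert a_mut[0].isodecoder == true_key
            checked += 1
        assert checked >= 10


class TestEndToEnd:
    def test_error_free_library_fully_assigned(self, sim_index, tmp_path):
        """Zero misincorporation: every non-spike read lands on its true isodecoder."""
        keys = sorted(sim_index.isodecoders)
        profile = ChargeProfile.from_dicts(
            {k: 0.6 for k in keys}, {k: 1.0 for k in keys}
        )
        params = LibraryParams(
            n_read_pairs=20_000, treatment=OXIDIZED, seed=13,
            spike_in_fraction=0.05, misincorporation_rate=0.0,
        )
        r1, r2, truth = simulate_read_library(sim_index, profile, params, tmp_path)
        _, counts = process_library(r1, r2, sim_index, sample_id="e2e")
        counts.check_conservation()
        assert counts.unassigned == 0
        assert counts.ambiguous == 0
        expected = dict(zip(truth["isodecoder"], truth["ligated_count"]))
        assert counts.spike_in == expected.pop("spike_in")
        assert counts.isodecoder_counts == {
            k: expected.get(k, 0) for k in counts.isodecoder_counts
        }
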