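import dataclasses

import numpy as np
import pytest

from recynh.library import LibraryEntry, Role, build_reference, reverse_complement
from recynh.mapping import (
    AdapterSpec,
    R1_Y2H,
    R2_Y2H,
    ReferenceIndex,
    align_to_reference,
    count_pairs,
    expected_rna_read1,
    filter_hit,
    match_rna_exact,
    min_exact_match_length,
    trim_adapter,
)
from recynh.simulate import SimConfig, simulate_fastq


class TestTrimAdapter:
    def test_exact_prefix_returns_insert(self):
        insert = "ACGTACGTACGTACGTACGT"
        assert trim_adapter(R1_Y2H + insert, R1_Y2H) == insert

    def test_short_insert_rejected(self):
        # inserts under 15 nt carry too little sequence to identify an ORF
        assert trim_adapter(R1_Y2H + "ACGTACGTAC", R1_Y2H) is None

    def test_mismatch_budget(self):
        insert = "ACGTACGTACGTACGTACGT"
        mutated = list(R1_Y2H)
        for pos in (3, 10, 20):
            mutated[pos] = "A" if mutated[pos] != "A" else "C"
        read = "".join(mutated) + insert
        assert trim_adapter(read, R1_Y2H, max_mm=2) is None
        assert trim_adapter(read, R1_Y2H, max_mm=3) == insert

    def test_read_shorter_than_adapter_rejected(self):
        assert trim_adapter(R1_Y2H[:20], R1_Y2H) is None

    def test_empty_read_is_an_error(self):
        with pytest.raises(ValueError):
            trim_adapter("", R1_Y2H)


class TestAlignToReference:
    def test_read_from_reference_maps_at_offset_zero(self, bait_refs):
        trimmed = bait_refs[0].ref_seq[:30]
        hit = align_to_reference(trimmed, bait_refs)
        assert hit is not None
        assert hit.target_id == bait_refs[0].target_id
        assert hit.ref_start_offset == 0
        assert hit.orientation == "forward"
        assert hit.e_value <= 1e-8

    def test_reverse_complement_read_flagged_reverse(self, bait_refs):
        trimmed = reverse_complement(bait_refs[1].ref_seq[:40])
        hit = align_to_reference(trimmed, bait_refs)
        assert hit is not None
        assert hit.target_id == bait_refs[1].target_id
        assert hit.orientation == "reverse"

    def test_tied_targets_are_ambiguous(self, bait_entries):
        # two targets sharing an identical 3' end: equal best scores
        twin = dataclasses.replace(bait_entries[0], id="twin")
        refs = build_reference([bait_entries[0], twin])
        assert align_to_reference(refs[0].ref_seq[:30], refs) is None

    def test_unrelated_read_has_no_hit(self, bait_refs, rng):
        # a random 30-mer sharing no 7-mer seed with any reference
        ref_kmers = {
            r.ref_seq[i : i + 7]
            for r in bait_refs
            for i in range(len(r.ref_seq) - 6)
        }
        bases = np.array(list("ACGT"))
        for _ in range(200):
            query = "".join(rng.choice(bases, size=30))
            if all(query[i : i + 7] not in ref_kmers for i in range(24)):
                assert align_to_reference(query, bait_refs) is None
                return
        pytest.fail("could not construct a seed-free query")

    def test_empty_reference_set_is_an_error(self):
        with pytest.raises(ValueError):
            align_to_reference("ACGT" * 10, [])

    def test_prefix_reads_map_for_all_targets_and_lengths(self, bait_refs):
        """A read taken as the first k bases of any reference maps to that
        reference at offset 0, for every k long enough that a perfect match
        can clear the E-value cut-off for this reference set."""
        index = ReferenceIndex(bait_refs)
        k_min = min_exact_match_length(index.total_ref_len)
        for ref in bait_refs:
            for k in range(k_min, len(ref.ref_seq) + 1, 13):
                hit = index.best_hit(ref.ref_seq[:k])
                assert hit is not None, (ref.target_id, k)
                assert hit.target_id == ref.target_id
                assert hit.ref_start_offset == 0
                assert hit.orientation == "forward"


class TestFilterHit:
    @pytest.mark.parametrize(
        "orientation,offset,accepted",
        [
            ("forward", 0, True),
            ("forward", 10, True),  # closed threshold
            ("forward", 15, False),  # too far from the 3' end
            ("reverse", 0, False),
        ],
    )
    def test_orientation_and_offset_rules(self, bait_refs, orientation, offset, accepted):
        from recynh.mapping import MappingHit

        hit = MappingHit(
            target_id="t", score=50, e_value=1e-20,
            ref_start_offset=offset, orientation=orientation,
        )
        assert filter_hit(hit) is accepted


class TestMatchRnaExact:
    @pytest.fixture
    def motifs(self):
        return [
            LibraryEntry(
                id=f"rna{i}", display_name=f"rna{i}", sequence=seq, role=Role.RNA_BAIT
            )
            for i, seq in enumerate(
                ["GGGCACGUACGC".replace("U", "T"), "AATTGGCCAATTGGCC", "TTTTCCCCGGGGAAAA"]
            )
        ]

    def test_exact_prefix_matches(self, motifs):
        trimmed = expected_rna_read1(motifs[0])[:15]
        assert match_rna_exact(trimmed, motifs) == "rna0"

    def test_single_substitution_fails(self, motifs):
        trimmed = list(expected_rna_read1(motifs[1])[:16])
        trimmed[8] = "A" if trimmed[8] != "A" else "C"
        assert match_rna_exact("".join(trimmed), motifs) is None

    def test_shared_motif_suffix_is_ambiguous(self, motifs):
        # read 1 enters the motif from its 3' side, so two motifs sharing a
        # 3'-terminal segment produce identical expected read-1 prefixes
        clone = LibraryEntry(
            id="clone",
            display_name="clone",
            sequence="ACGT" + motifs[2].sequence,
            role=Role.RNA_BAIT,
        )
        probe = expected_rna_read1(motifs[2])[:15]
        assert expected_rna_read1(clone).startswith(probe)
        assert match_rna_exact(probe, [clone, motifs[2]]) is None


class TestCountPairs:
    def _write_pairs(self, tmp_path, rows):
        r1 = tmp_path / "r1.fastq"
        r2 = tmp_path / "r2.fastq"
        with open(r1, "w") as h1, open(r2, "w") as h2:
            for i, (seq1, seq2) in enumerate(rows):
                h1.write(f"@p{i}\n{seq1}\n+\n{'I' * len(seq1)}\n")
                h2.write(f"@p{i}\n{seq2}\n+\n{'I' * len(seq2)}\n")
        return r1, r2

    def test_noiseless_single_pair(self, tmp_path, bait_refs, prey_refs):
        read1 = R1_Y2H + bait_refs[1].ref_seq[:40]
        read2 = R2_Y2H + prey_refs[2].ref_seq[:40]
        r1, r2 = self._write_pairs(tmp_path, [(read1, read2)] * 100)
        matrix, stats = count_pairs(
            r1, r2, AdapterSpec.y2h(), bait_refs=bait_refs, prey_refs=prey_refs
        )
        assert matrix[bait_refs[1].target_id, prey_refs[2].target_id] == 100
        assert matrix.values.sum() == 100
        assert stats.usable_fraction == 1.0

    def test_missing_read2_adapter_gives_no_usable_pairs(
        self, tmp_path, bait_refs, prey_refs
    ):
        read1 = R1_Y2H + bait_refs[0].ref_seq[:40]
        read2 = "T" * 40  # no adapter at all
        r1, r2 = self._write_pairs(tmp_path, [(read1, read2)] * 20)
        matrix, stats = count_pairs(
            r1, r2, AdapterSpec.y2h(), bait_refs=bait_refs, prey_refs=prey_refs
        )
        assert stats.usable_pairs == 0
        assert stats.adapter_pass_pairs == 0
        assert matrix.values.sum() == 0

    def test_desynchronised_mates_are_an_error(self, tmp_path, bait_refs, prey_refs):
        r1 = tmp_path / "r1.fastq"
        r2 = tmp_path / "r2.fastq"
        r1.write_text("@a\nACGT\n+\nIIII\n")
        r2.write_text("@b\nACGT\n+\nIIII\n")
        with pytest.raises(ValueError, match="desynchronised"):
            count_pairs(
                r1, r2, AdapterSpec.y2h(), bait_refs=bait_refs, prey_refs=prey_refs
            )

    def test_pair_fates_partition_and_are_deterministic(
        self, tmp_path, bait_refs, prey_refs, rng
    ):
        # a mix of valid pairs, adapter failures, and unmappable inserts
        bases = np.array(list("ACGT"))
        rows = []
        for i in range(30):
            if i % 3 == 0:
                rows.append(
                    (
                        R1_Y2H + bait_refs[i % 4].ref_seq[:35],
                        R2_Y2H + prey_refs[i % 5].ref_seq[:35],
                    )
                )
            elif i % 3 == 1:
                rows.append(("A" * 90, R2_Y2H + prey_refs[0].ref_seq[:35]))
            else:
                rows.append(
                    (
                        R1_Y2H + "".join(rng.choice(bases, size=40)),
                        R2_Y2H + prey_refs[1].ref_seq[:35],
                    )
                )
        r1, r2 = self._write_pairs(tmp_path, rows)
        spec = AdapterSpec.y2h()
        matrix1, stats1 = count_pairs(
            r1, r2, spec, bait_refs=bait_refs, prey_refs=prey_refs
        )
        matrix2, stats2 = count_pairs(
            r1, r2, spec, bait_refs=bait_refs, prey_refs=prey_refs
        )
        assert stats1.total_pairs == 30
        assert stats1.usable_pairs == matrix1.values.sum()
        assert stats1.usable_pairs <= stats1.adapter_pass_pairs <= stats1.total_pairs
        # deterministic: identical inputs, identical outputs
        assert (matrix1.values == matrix2.values).all()
        assert stats1 == stats2


def test_error_free_simulated_reads_round_trip_exactly(tmp_path):
    """Mapping error-free simulated FASTQ reproduces the simulated counts."""
    cfg = SimConfig(
        n_baits=6,
        n_preys=6,
        interactions=(("BAIT001", "PREY002", 40.0),),
        reads_per_condition=400,
        per_base_error=0.0,
        seed=5,
    )
    sim = simulate_fastq(cfg, tmp_path)
    spec = cfg.adapter_spec()
    for r1, r2, expected in (
        (sim.rs_r1, sim.rs_r2, sim.counts_rs),
        (sim.ris_r1, sim.ris_r2, sim.counts_ris),
    ):
        matrix, stats = count_pairs(
            r1,
            r2,
            spec,
            bait_refs=sim.truth.bait_references(),
            prey_refs=sim.truth.prey_references(),
        )
        assert matrix.baits == expected.baits
        assert matrix.preys == expected.preys
        assert (matrix.values == expected.values).all()
        assert stats.usable_fraction == 1.0


def test_sequencing_errors_reduce_usable_fraction(tmp_path):
    cfg = SimConfig(
        n_baits=4, n_preys=4, reads_per_condition=150, per_base_error=0.0, seed=9
    )
    noisy = dataclasses.replace(cfg, per_base_error=0.1)
    fractions = []
    for c, sub in ((cfg, "clean"), (noisy, "noisy")):
        sim = simulate_fastq(c, tmp_path / sub, seed=9)
        _, stats = count_pairs(
            sim.rs_r1,
            sim.rs_r2,
            c.adapter_spec(),
            bait_refs=sim.truth.bait_references(),
            prey_refs=sim.truth.prey_references(),
        )
        fractions.append(stats.usable_fraction)
    assert fractions[1] < fractions[0]
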