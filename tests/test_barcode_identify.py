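"""Trimming, alignment, consensus, hit curation, assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from labelaudit.barcode_identify import (
    FilterConfig,
    TrimConfig,
    align_pair,
    assign_species,
    call_consensus,
    filter_hits,
    identify_cohort,
    reverse_complement,
    trim_read,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


class TestTrim:
    def test_long_clean_read_capped_at_max_len(self):
        seq = "A" * 300
        out = trim_read(seq, [40] * 300, TrimConfig())
        assert out is not None and len(out[0]) == min(300 - 30, 250) == 250

    def test_short_read_rejected_after_front_trim(self):
        assert trim_read("A" * 120, [40] * 120, TrimConfig()) is None  # 90 < 100

    def test_low_quality_tail_removed_matches_window_oracle(self):
        cfg = TrimConfig()
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(140, 320))
            qual = [40] * n
            tail = int(rng.integers(0, 80))
            if tail:
                qual[-tail:] = [10] * tail
            seq = "".join(rng.choice(list("ACGT"), n))

            def oracle(seq, qual):
                s, q = seq[cfg.front_trim:], qual[cfg.front_trim:]
                end = len(s)
                while end > 0:
                    w = min(cfg.window, end)
                    if float(np.mean(q[end - w : end])) < cfg.qual_floor:
                        end -= w
                    else:
                        break
                s, q = s[: min(end, cfg.max_len)], q[: min(end, cfg.max_len)]
                if len(s) < cfg.min_len or float(np.mean(q)) < cfg.qual_floor:
                    return None
                return s, q

            assert trim_read(seq, qual, cfg) == oracle(seq, qual)

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError):
            trim_read("ACGT", [40] * 3)


class TestReverseComplement:
    @pytest.mark.parametrize("seq,expected", [("ACGT", "ACGT"), ("AAAC", "GTTT"), ("N", "N")])
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    @settings(derandomize=True, max_examples=100)
    @given(dna)
    def test_involution(self, seq):
        qual = list(range(len(seq)))
        s1, q1 = reverse_complement(seq, qual)
        s2, q2 = reverse_complement(s1, q1)
        assert s2 == seq and q2 == qual

    def test_invalid_character_raises(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGX")


class TestAlign:
    def test_identical_reads_align_gapless(self):
        a, b, score = align_pair("ACGTACGT", "ACGTACGT")
        assert a == b == "ACGTACGT" and score == 8

    def test_single_gap_column(self):
        a, b, score = align_pair("ACGT", "AGT")
        assert (a, b) == ("ACGT", "A-GT")
        assert score == 3 - 2

    def test_score_matches_independent_aligner(self):
        """Scores equal Biopython's optimal global aligner on random 60-mers."""
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        rng = np.random.default_rng(17)
        for _ in range(100):
            x = "".join(rng.choice(list("ACGT"), 60))
            y = "".join(rng.choice(list("ACGT"), 60))
            _, _, score = align_pair(x, y)
            assert score == aligner.score(x, y)

    def test_alignment_is_valid_and_scores_itself(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = "".join(rng.choice(list("ACGT"), 50))
            y = "".join(rng.choice(list("ACGT"), 45))
            a, b, score = align_pair(x, y)
            assert a.replace("-", "") == x and b.replace("-", "") == y
            recomputed = sum(
                -2 if "-" in (ca, cb) else (1 if ca == cb else -1)
                for ca, cb in zip(a, b)
            )
            assert recomputed == score


class TestConsensus:
    def test_agreement_emits_shared_base(self):
        c = call_consensus("A", "A", [30], [20])
        assert c.seq == "A" and c.pair_disagreements == 0

    def test_disagreement_takes_higher_quality(self):
        c = call_consensus("A", "G", [35], [20])
        assert c.seq == "A" and c.pair_disagreements == 1
        c = call_consensus("A", "G", [20], [35])
        assert c.seq == "G"

    def test_quality_tie_emits_n(self):
        assert call_consensus("A", "G", [30], [30]).seq == "N"

    def test_gap_columns_emit_nongap_base(self):
        c = call_consensus("AC-T", "A-GT", [40, 5, 40], [5, 40, 5])
        assert c.seq == "ACGT"

    def test_matches_columnwise_oracle_on_random_pairs(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            n = int(rng.integers(20, 80))
            x = "".join(rng.choice(list("ACGT"), n))
            y = "".join(rng.choice(list("ACGT"), int(rng.integers(15, 80))))
            qa = [int(q) for q in rng.integers(2, 41, len(x))]
            qb = [int(q) for q in rng.integers(2, 41, len(y))]
            a, b, _ = align_pair(x, y)
            got = call_consensus(a, b, qa, qb)

            # independent per-column walk
            seq, i, j, dis = [], 0, 0, 0
            for ca, cb in zip(a, b):
                if ca != "-" and cb != "-":
                    if ca == cb:
                        seq.append(ca)
                    else:
                        dis += 1
                        if qa[i] > qb[j]:
                            seq.append(ca)
                        elif qb[j] > qa[i]:
                            seq.append(cb)
                        else:
                            seq.append("N")
                    i, j = i + 1, j + 1
                elif ca != "-":
                    seq.append(ca)
                    i += 1
                else:
                    seq.append(cb)
                    j += 1
            assert got.seq == "".join(seq) and got.pair_disagreements == dis


def hit_row(**kw):
    base = dict(
        qseqid="q1",
        species="Aus aus",
        db="NCBI",
        identity=99.5,
        coverage=99.0,
        evalue=1e-30,
        species_db_entries=100,
    )
    base.update(kw)
    return base


class TestFilterHits:
    def test_identity_below_cutoff_removed(self):
        h = pd.DataFrame([hit_row(identity=97.5)])
        assert filter_hits(h).empty

    def test_entry_fraction_rule(self):
        # 3 hits out of 500 entries = 0.6% < 1% -> removed
        h = pd.DataFrame([hit_row(species_db_entries=500)] * 3)
        assert filter_hits(h).empty
        # 6/500 = 1.2% -> retained
        h = pd.DataFrame([hit_row(species_db_entries=500)] * 6)
        assert len(filter_hits(h)) == 6

    def test_single_entry_species_removed(self):
        h = pd.DataFrame([hit_row(species_db_entries=1)])
        assert filter_hits(h).empty
        cfg = FilterConfig(drop_single_entry_species=False)
        assert len(filter_hits(h, cfg)) == 1

    def test_supraspecific_names_removed(self):
        h = pd.DataFrame([hit_row(species="Carcharhinus sp."), hit_row()])
        out = filter_hits(h)
        assert list(out["species"]) == ["Aus aus"]

    def test_idempotent_and_order_independent(self):
        rng = np.random.default_rng(5)
        rows = [
            hit_row(species=f"Sp {i%4}", identity=float(rng.uniform(96, 100)),
                    coverage=float(rng.uniform(96, 100)),
                    species_db_entries=int(rng.integers(1, 300)))
            for i in range(40)
        ]
        h = pd.DataFrame(rows)
        once = filter_hits(h)
        twice = filter_hits(once)
        pd.testing.assert_frame_equal(once, twice)
        shuffled = h.sample(frac=1, random_state=1).reset_index(drop=True)
        out_shuffled = filter_hits(shuffled).sort_values(list(h.columns)).reset_index(drop=True)
        out_orig = once.sort_values(list(h.columns)).reset_index(drop=True)
        pd.testing.assert_frame_equal(out_orig, out_shuffled)

    def test_missing_entry_count_raises(self):
        h = pd.DataFrame([hit_row(species_db_entries=np.nan)])
        with pytest.raises(ValueError):
            filter_hits(h)


class TestAssign:
    def test_single_surviving_species_assigned(self):
        h = filter_hits(pd.DataFrame([hit_row()] * 2))
        call = assign_species(h, "s1")
        assert call.status == "assigned" and call.species == "Aus aus"

    def test_exclusion_list_gives_contamination(self):
        h = filter_hits(pd.DataFrame([hit_row(species="Sus scrofa")] * 2))
        call = assign_species(h, "s1", exclusion_list={"Sus scrofa"})
        assert call.status == "contamination_excluded" and call.species is None

    def test_tie_flags_ambiguity_alphabetical_winner_any_order(self):
        rows = [
            hit_row(species="Bus bus", identity=99.0, coverage=99.0),
            hit_row(species="Aus aus", identity=99.0, coverage=99.0),
        ] * 2
        import itertools

        for perm in itertools.permutations(range(4)):
            h = filter_hits(pd.DataFrame([rows[i] for i in perm]))
            call = assign_species(h, "s1")
            assert call.species == "Aus aus" and call.ambiguous

    def test_empty_after_filter_is_low_confidence(self):
        h = filter_hits(pd.DataFrame([hit_row(identity=90.0)]))
        assert assign_species(h, "s1", had_raw_hits=True).status == "low_confidence"
        assert assign_species(h, "s1", had_raw_hits=False).status == "no_hits"


class TestPipeline:
    def test_cohort_deterministic_and_statuses(self):
        from labelaudit.barcode_identify import consensus_cohort
        from labelaudit.synthetic_data import (
            StudyDesign,
            generate_hit_tables,
            generate_products,
            generate_reads,
            generate_refdb,
        )

        _, truth = generate_products(StudyDesign(seed=6, n_states=1, samples_per_state=30))
        refdb = generate_refdb(seed=6)
        reads = generate_reads(truth, refdb, error_rate=0.001, seed=6, dropout_frac=0.1)
        cons = consensus_cohort(reads)
        hits = generate_hit_tables(cons, refdb, {s: 50 for s in refdb}, seed=6)
        a = identify_cohort(reads, hits)
        b = identify_cohort(reads, hits)
        pd.testing.assert_frame_equal(a, b)
        assert (a.loc[a["status"] == "no_amplification", "sample_id"].tolist()
                == [sid for sid in sorted(reads) if reads[sid] is None])

    def test_error_free_reads_recover_true_species(self):
        """With error-free reads and a complete reference db, nearly every
        sample is assigned its true species (n=500)."""
        from labelaudit.barcode_identify import consensus_cohort
        from labelaudit.synthetic_data import (
            StudyDesign,
            generate_hit_tables,
            generate_products,
            generate_reads,
            generate_refdb,
        )

        _, truth = generate_products(StudyDesign(seed=13, n_states=5, samples_per_state=100))
        refdb = generate_refdb(seed=13)
        reads = generate_reads(truth, refdb, error_rate=0.0, seed=13)
        cons = consensus_cohort(reads)
        hits = generate_hit_tables(cons, refdb, {s: 50 for s in refdb}, seed=13)
        calls = identify_cohort(reads, hits)
        m = calls.merge(truth, on="sample_id")
        correct = (m["status"] == "assigned") & (
            m["species"].str.lower() == m["true_species"].str.lower()
        )
        assert correct.mean() >= 0.99
        # every assignment is backed only by hits above the identity cutoff
        assigned_ids = set(m.loc[m["status"] == "assigned", "sample_id"])
        surviving = filter_hits(hits[hits["qseqid"].isin(assigned_ids)])
        assert (surviving["identity"] >= 98.0).all()

    def test_assigned_calls_only_from_high_identity_hits(self):
        """Every surviving hit behind an assignment clears 98% identity."""
        h = pd.DataFrame([hit_row(identity=98.0), hit_row(identity=99.9)])
        out = filter_hits(h)
        assert (out["identity"] >= 98.0).all()
        assert assign_species(out, "s").status == "assigned"
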