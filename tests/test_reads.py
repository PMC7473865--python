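import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from groovescan.reads import (RawCountTable, collapse_errors, filter_reads,
                              process_rounds, translate_and_tabulate)
from groovescan.simulate import sample_naive


def _hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


def collapse_oracle(counts):
    """O(n^2) all-pairs reference for the tiered Hamming error collapse."""
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    retained = []
    for s, c in items:
        discard = False
        for t, ct in retained:
            if ct <= c:
                continue
            d = _hamming(s, t)
            if d <= 1 or (d <= 2 and ct >= 100 * c) or (d <= 3 and ct >= 10_000 * c):
                discard = True
                break
        if not discard:
            retained.append((s, c))
    return dict(retained)


def random_count_table(rng, n_seqs, length):
    """Clustered random table: error children planted near high-count parents."""
    counts = {}
    n_parents = max(1, n_seqs // 5)
    bases = np.array(list("ACGT"))
    parents = set()
    while len(parents) < n_parents:
        parents.add("".join(rng.choice(bases, size=length)))
    parents = sorted(parents)
    for p in parents:
        counts[p] = int(10 ** rng.uniform(0, 4.5))
    while len(counts) < n_seqs:
        p = parents[rng.integers(len(parents))]
        n_mut = int(rng.integers(1, 4))
        s = list(p)
        for pos in rng.choice(length, size=n_mut, replace=False):
            s[pos] = bases[rng.integers(4)]
        s = "".join(s)
        if s not in counts:
            counts[s] = int(10 ** rng.uniform(0, 2))
    return counts


class TestFilterReads:
    def _one_read(self, design, seed=1):
        reads = sample_naive(design, 1, seed=seed)
        return reads.records[0]

    def test_clean_read_kept(self, design9):
        dna, qual = self._one_read(design9)
        tables, att = filter_reads([(dna, qual)], design9)
        assert att["kept"] == 1 and 0 in tables

    def test_low_quality_peptide_base_discarded(self, design9):
        dna, qual = self._one_read(design9)
        pep_start = design9.barcode_length + len(design9.constant5_dna)
        bad = qual[:pep_start] + chr(33 + 19) + qual[pep_start + 1:]
        _, att = filter_reads([(dna, bad)], design9)
        assert att["low_quality"] == 1 and att.get("kept", 0) == 0
        # Phred exactly 20 is kept
        ok = qual[:pep_start] + chr(33 + 20) + qual[pep_start + 1:]
        _, att = filter_reads([(dna, ok)], design9)
        assert att["kept"] == 1

    def test_low_quality_outside_peptide_ignored(self, design9):
        dna, qual = self._one_read(design9)
        bad = chr(33 + 2) + qual[1:]  # barcode base at Q2
        _, att = filter_reads([(dna, bad)], design9)
        assert att["kept"] == 1

    def test_non_nnk_codon_discarded(self, design9):
        dna, qual = self._one_read(design9)
        pep_start = design9.barcode_length + len(design9.constant5_dna)
        rs = design9.randomized_slice
        third = pep_start + 3 * rs.start + 2
        bad = dna[:third] + "A" + dna[third + 1:]  # K must be G or T
        _, att = filter_reads([(bad, qual)], design9)
        assert att["bad_nnk"] == 1
        ok = dna[:third] + "G" + dna[third + 1:]
        _, att = filter_reads([(ok, qual)], design9)
        assert att["kept"] == 1

    def test_wrong_length_discarded(self, design9):
        dna, qual = self._one_read(design9)
        _, att = filter_reads([(dna[:-1], qual[:-1])], design9)
        assert att["bad_length"] == 1

    def test_constant_mismatch_discarded(self, design9):
        dna, qual = self._one_read(design9)
        mut = dna[:-1] + ("A" if dna[-1] != "A" else "C")
        _, att = filter_reads([(mut, qual)], design9)
        assert att["bad_constant"] == 1

    def test_unknown_barcode_discarded(self, design9):
        dna, qual = self._one_read(design9)
        bad = "N" * design9.barcode_length + dna[design9.barcode_length:]
        _, att = filter_reads([(bad, qual)], design9)
        assert att["bad_barcode"] == 1

    def test_malformed_record_raises(self, design9):
        dna, qual = self._one_read(design9)
        with pytest.raises(ValueError, match="malformed FASTQ record"):
            filter_reads([(dna, qual[:-2])], design9)


class TestCollapseErrors:
    def test_error_child_collapsed(self):
        parent = "A" * 30
        child = "C" + "A" * 29
        table = RawCountTable(0, {parent: 10_000, child: 3})
        out = collapse_errors(table)
        assert out.counts == {parent: 10_000}

    def test_single_sequence_retained(self):
        table = RawCountTable(0, {"ACGTACGTA": 1})
        assert collapse_errors(table).counts == {"ACGTACGTA": 1}

    def test_ratio_below_gates_both_retained(self):
        a = "AAAAAAAAA"
        b = "CCCAAAAAA"  # Hamming 3
        table = RawCountTable(0, {a: 50, b: 1})
        out = collapse_errors(table)
        assert set(out.counts) == {a, b}

    def test_radius2_requires_100x(self):
        a = "AAAAAAAAA"
        b = "CCAAAAAAA"  # Hamming 2
        out = collapse_errors(RawCountTable(0, {a: 99, b: 1}))
        assert set(out.counts) == {a, b}
        out = collapse_errors(RawCountTable(0, {a: 100, b: 1}))
        assert set(out.counts) == {a}

    def test_equal_counts_never_collapse(self):
        a = "AAAAAAAAA"
        b = "CAAAAAAAA"
        out = collapse_errors(RawCountTable(0, {a: 5, b: 5}))
        assert set(out.counts) == {a, b}

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            counts = random_count_table(rng, int(rng.integers(5, 120)), 12)
            ours = collapse_errors(RawCountTable(0, counts)).counts
            assert ours == collapse_oracle(counts)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.dictionaries(st.text(alphabet="ACGT", min_size=6, max_size=6),
                           st.integers(min_value=1, max_value=20_000),
                           min_size=1, max_size=25))
    def test_matches_oracle_property(self, counts):
        ours = collapse_errors(RawCountTable(0, counts)).counts
        assert ours == collapse_oracle(counts)

    def test_all_pairs_variant_matches_its_own_oracle(self):
        # config switch: compare against all more prevalent, not only retained
        rng = np.random.default_rng(7)
        counts = random_count_table(rng, 60, 10)
        ours = collapse_errors(RawCountTable(0, counts), compare_retained_only=False).counts
        items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        expect = {}
        for s, c in items:
            hit = any(ct > c and (
                _hamming(s, t) <= 1
                or (_hamming(s, t) <= 2 and ct >= 100 * c)
                or (_hamming(s, t) <= 3 and ct >= 10_000 * c))
                for t, ct in counts.items())
            if not hit:
                expect[s] = c
        assert ours == expect


class TestTranslateAndTabulate:
    def test_stop_codon_dropped(self, design9):
        f5, f3 = design9.flank_dna()
        dna_stop = f5 + "TAG" + "GCT" * 8 + f3
        tables = {0: RawCountTable(0, {dna_stop: 5})}
        out = translate_and_tabulate(tables, design9)
        assert len(out) == 0

    def test_synonymous_merge(self, design9):
        f5, f3 = design9.flank_dna()
        dna1 = f5 + "CTG" + "GCT" * 8 + f3  # Leu codon 1
        dna2 = f5 + "CTT" + "GCT" * 8 + f3  # Leu codon 2
        tables = {0: RawCountTable(0, {dna1: 5, dna2: 7})}
        out = translate_and_tabulate(tables, design9)
        assert len(out) == 1
        assert out["reads_r0"].iloc[0] == 12
        assert out["peptide"].iloc[0] == "AA" + "L" + "A" * 8 + "WEEG"

    def test_standard_code(self, design9):
        f5, f3 = design9.flank_dna()
        dna = f5 + "ATGGCT" + "GGT" * 7 + f3
        out = translate_and_tabulate({0: RawCountTable(0, {dna: 1})}, design9)
        assert out["peptide"].iloc[0][2:4] == "MA"

    def test_final_round(self, design9):
        f5, f3 = design9.flank_dna()
        dna = f5 + "GCT" * 9 + f3
        tables = {0: RawCountTable(0, {dna: 3}),
                  1: RawCountTable(1, {dna: 2}),
                  2: RawCountTable(2, {})}
        out = translate_and_tabulate(tables, design9)
        assert out["final_round"].iloc[0] == 1

    def test_frame_error(self, design9):
        with pytest.raises(ValueError, match="frame error"):
            translate_and_tabulate({0: RawCountTable(0, {"ACGT": 1})}, design9)


class TestPipelineConservation:
    def test_no_stage_creates_reads_or_peptides(self, design9):
        from groovescan.simulate import (annotate_truth, default_ground_truth,
                                         inject_errors, simulate_selection)
        model = default_ground_truth(design9)
        naive = sample_naive(design9, 3000, seed=31)
        annotate_truth(naive, design9, model, 32)
        rounds = simulate_selection(naive, model, 2, carryover=3000, seed=33,
                                    design=design9)
        noisy = [inject_errors(rs, 1e-3, 0.02, 34 + i)
                 for i, rs in enumerate([naive] + rounds)]
        n_in = sum(len(rs.records) for rs in noisy)
        table, att = process_rounds(noisy, design9)
        n_out = sum(table[f"reads_r{r}"].sum() for r in range(3))
        assert n_out <= n_in
        truth_peps = {v[0] for rs in noisy for v in rs.truth.values()}
        # every reported peptide is either a truth peptide or an
        # uncollapsed error child -- but never invented from nothing
        reported = set(table["peptide"])
        from groovescan.simulate import translate_codons
        import numpy as np
        pep_start = design9.barcode_length + len(design9.constant5_dna)
        pep_end = pep_start + 3 * design9.peptide_length
        possible = set()
        for rs in noisy:
            for d, _ in rs.records:
                region = d[pep_start:pep_end]
                arr = np.frombuffer(region.encode(), np.uint8)[None, :]
                possible.add(translate_codons(arr).tobytes().decode())
        assert reported <= possible
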