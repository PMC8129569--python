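"""Clonality contracts: read merging, demultiplexing, clonotype
aggregation, top-clone reports, dominant isoform matching, and the exact
rank-sum test against a brute-force oracle."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from lplpipe import clonality, synthio
from lplpipe.clonality import (
    MergedRead,
    build_clonotypes,
    demultiplex,
    dominant_isoform_match,
    merge_read_pair,
    ranksum_exact,
    top_clone_frequencies,
)


def _revcomp(seq):
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _pair_from_template(template, read_len, q=30):
    r1 = (template[:read_len], [q] * read_len)
    r2 = (_revcomp(template[-read_len:]), [q] * read_len)
    return r1, r2


class TestMergeReadPair:
    def test_perfect_overlap_reconstructs_template(self):
        rng = np.random.default_rng(1)
        template = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)])
        r1, r2 = _pair_from_template(template, 45)  # 30-nt overlap
        merged = merge_read_pair(r1, r2)
        assert merged is not None and merged.sequence == template

    def test_excess_mismatch_density_fails(self):
        # 20-nt overlap with 6 mismatches: density 0.3 > 0.25, no shorter
        # alternative overlap can qualify by construction
        left = "A" * 40
        overlap_r1 = "ACGTACGTACGTACGTACGT"
        overlap_r2 = "TCGATCGTAGGTACCTACCT"  # 6 mismatches vs overlap_r1
        r1 = (left + overlap_r1, [30] * 60)
        r2 = (_revcomp(overlap_r2 + "G" * 40), [30] * 60)
        assert merge_read_pair(r1, r2, min_overlap=20) is None

    def test_consensus_takes_higher_quality_base(self):
        rng = np.random.default_rng(12)
        template = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 30)])
        r1_list = list(template[:20])
        # corrupt one base inside the 10-nt overlap, low quality on read 1
        r1_list[12] = {"A": "C", "C": "A", "G": "T", "T": "G"}[r1_list[12]]
        r1 = ("".join(r1_list), [10] * 20)
        r2 = (_revcomp(template[10:]), [40] * 20)
        merged = merge_read_pair(r1, r2, min_overlap=8)
        assert merged is not None
        assert merged.sequence == template  # quality-40 read2 base wins

    def test_empty_read_rejected(self):
        with pytest.raises(ValueError):
            merge_read_pair(("", []), ("ACGT", [30] * 4))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_merge_round_trip_random_templates(seed):
    """Reads cut from a random template with a clean overlap always merge
    back to the template."""
    rng = np.random.default_rng(seed)
    tlen = int(rng.integers(50, 90))
    read_len = int(rng.integers(max(30, tlen - 35), min(tlen, 60)))
    template = "".join(np.array(list("ACGT"))[rng.integers(0, 4, tlen)])
    if 2 * read_len - tlen < 10:
        return  # overlap below the merger's minimum
    r1, r2 = _pair_from_template(template, read_len)
    merged = merge_read_pair(r1, r2)
    assert merged is not None and merged.sequence == template


class TestDemultiplex:
    BARCODES = {"AAAAACCC": "s1", "GGGGGTTT": "s2"}
    PRIMERS = {
        "ACGTACGTACGTACGTACGT": ("mu", "membrane"),
        "TTTTGGGGCCCCAAAATTTT": ("mu", "secreted"),
    }

    def _read(self, barcode, primer, middle="ACACACACAC"):
        seq = barcode + middle + primer
        return MergedRead(seq, [30] * len(seq))

    def test_exact_assignment(self):
        reads = [self._read("AAAAACCC", "ACGTACGTACGTACGTACGT")]
        out, tally = demultiplex(reads, self.BARCODES, self.PRIMERS)
        assert tally["assigned"] == 1
        assert (out[0].sample_id, out[0].chain, out[0].isoform) == ("s1", "mu", "membrane")
        assert out[0].trimmed == "ACACACACAC"

    def test_one_primer_mismatch_tolerated_two_rejected(self):
        one = "ACGTACGTACGTACGTACGA"  # 1 mismatch
        two = "ACGTACGTACGTACGTACAA"  # 2 mismatches
        reads = [self._read("AAAAACCC", one), self._read("AAAAACCC", two)]
        out, tally = demultiplex(reads, self.BARCODES, self.PRIMERS)
        assert tally["assigned"] == 1 and tally["no_primer"] == 1

    def test_unknown_barcode_dropped(self):
        reads = [self._read("CCCCCCCC", "ACGTACGTACGTACGTACGT")]
        out, tally = demultiplex(reads, self.BARCODES, self.PRIMERS)
        assert out == [] and tally["no_barcode"] == 1

    def test_empty_input(self):
        out, tally = demultiplex([], self.BARCODES, self.PRIMERS)
        assert out == [] and tally["assigned"] == 0


class TestBuildClonotypes:
    def _airr(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "sequence_id", "v_call", "j_call", "junction",
                "duplicate_count", "sample_id", "chain", "isoform",
            ],
        )

    def test_counts_sum_within_key(self):
        airr = self._airr(
            [
                ("r1", "IGHV1", "IGHJ1", "ACGT", 3, "s1", "mu", "membrane"),
                ("r2", "IGHV1", "IGHJ1", "ACGT", 4, "s1", "mu", "membrane"),
            ]
        )
        table = build_clonotypes(airr)
        assert len(table) == 1 and table["count"].iloc[0] == 7

    def test_isoforms_are_separate_libraries(self):
        airr = self._airr(
            [
                ("r1", "IGHV1", "IGHJ1", "ACGT", 3, "s1", "mu", "membrane"),
                ("r2", "IGHV1", "IGHJ1", "ACGT", 4, "s1", "mu", "secreted"),
            ]
        )
        table = build_clonotypes(airr)
        assert len(table) == 2

    def test_invalid_junction_rejected_with_row(self):
        airr = self._airr(
            [("r1", "IGHV1", "IGHJ1", "ACXT", 3, "s1", "mu", "membrane")]
        )
        with pytest.raises(ValueError, match="row"):
            build_clonotypes(airr)

    def test_missing_columns_named(self):
        with pytest.raises(ValueError, match="junction"):
            build_clonotypes(pd.DataFrame({"v_call": ["x"]}))


class TestTopCloneFrequencies:
    def _table(self, counts, sample="s1", chain="mu", isoform="membrane"):
        return pd.DataFrame(
            [
                {
                    "sample_id": sample, "chain": chain, "isoform": isoform,
                    "v_call": "IGHV1", "j_call": "IGHJ1", "junction": j, "count": c,
                }
                for j, c in counts.items()
            ]
        )

    def test_single_clone_library(self):
        rep = top_clone_frequencies(self._table({"AAAA": 10}))
        assert rep.top_clones("s1", "mu", "membrane") == [(("IGHV1", "IGHJ1", "AAAA"), 1.0)]

    def test_hand_normalization(self):
        rep = top_clone_frequencies(self._table({"AAAA": 50, "CCCC": 30, "GGGG": 20}))
        freqs = [f for _, f in rep.top_clones("s1", "mu", "membrane")]
        assert freqs == pytest.approx([0.5, 0.3, 0.2])

    def test_truncation_bound(self):
        rep = top_clone_frequencies(self._table({"AAAA": 5, "CCCC": 3, "GGGG": 2}), n_top=5)
        assert len(rep.top_clones("s1", "mu", "membrane")) == 3

    def test_frequencies_sum_to_one_before_truncation(self):
        table, _ = synthio.simulate_repertoire([("s1", True, 0.5)], n_reads=1000, seed=2)
        rep = top_clone_frequencies(table)
        for lib in rep.libraries.values():
            total = sum(lib["counts"].values())
            assert sum(c / total for c in lib["counts"].values()) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_tie_broken_lexicographically(self):
        rep = top_clone_frequencies(self._table({"CCCC": 5, "AAAA": 5}), n_top=1)
        assert rep.dominant_key("s1", "mu", "membrane") == ("IGHV1", "IGHJ1", "AAAA")


class TestDominantIsoformMatch:
    def test_full_key_comparison(self):
        rows = []
        for isoform, v in (("membrane", "IGHV1"), ("secreted", "IGHV2")):
            rows.append(
                {
                    "sample_id": "s1", "chain": "mu", "isoform": isoform,
                    "v_call": v, "j_call": "IGHJ1", "junction": "ACGT", "count": 9,
                }
            )
        rep = top_clone_frequencies(pd.DataFrame(rows))
        assert dominant_isoform_match(rep, "s1", "mu") is False  # same junction, different V

    def test_missing_isoform_library_errors(self):
        rep = top_clone_frequencies(
            pd.DataFrame(
                [
                    {
                        "sample_id": "s1", "chain": "mu", "isoform": "membrane",
                        "v_call": "IGHV1", "j_call": "IGHJ1", "junction": "ACGT", "count": 9,
                    }
                ]
            )
        )
        with pytest.raises(KeyError):
            dominant_isoform_match(rep, "s1", "mu")

    def test_truth_driven_recovery(self):
        """Clonal samples always match; polyclonal samples match only at
        chance level (at most 2 of 20 seeds)."""
        clonal_hits = poly_hits = 0
        for seed in range(20):
            table, _ = synthio.simulate_repertoire(
                [("clo", True, 0.6), ("pol", False, 0.0)],
                n_reads=1000, chains=("mu",), seed=seed,
            )
            rep = top_clone_frequencies(table)
            clonal_hits += dominant_isoform_match(rep, "clo", "mu")
            poly_hits += dominant_isoform_match(rep, "pol", "mu")
        assert clonal_hits == 20
        assert poly_hits <= 2


def _ranksum_bruteforce(x, y, alternative):
    pooled = np.array(list(x) + list(y), dtype=float)
    n = len(x)
    ranks = rankdata(pooled)
    w_obs = ranks[:n].sum()
    sums = [sum(ranks[list(c)]) for c in combinations(range(len(pooled)), n)]
    sums = np.array(sums)
    p_less = (sums <= w_obs + 1e-9).mean()
    p_greater = (sums >= w_obs - 1e-9).mean()
    if alternative == "less":
        return min(1.0, p_less)
    if alternative == "greater":
        return min(1.0, p_greater)
    return min(1.0, 2 * min(p_less, p_greater))


class TestRanksumExact:
    def test_hand_enumeration(self):
        assert ranksum_exact([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_multisets_give_one(self):
        assert ranksum_exact([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_matches_scipy_without_ties(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=4).tolist()
            y = rng.normal(size=5).tolist()
            for alt in ("two-sided", "less", "greater"):
                ours = ranksum_exact(x, y, alt)
                ref = mannwhitneyu(x, y, alternative=alt, method="exact").pvalue
                assert ours == pytest.approx(ref, abs=1e-12)

    def test_matches_bruteforce_oracle_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n = int(rng.integers(1, 5))
            m = int(rng.integers(1, 8 - n + 1))
            x = rng.integers(0, 4, n).astype(float).tolist()
            y = rng.integers(0, 4, m).astype(float).tolist()
            for alt in ("two-sided", "less", "greater"):
                assert ranksum_exact(x, y, alt) == pytest.approx(
                    _ranksum_bruteforce(x, y, alt), abs=1e-12
                )

    def test_normal_approximation_close_to_exact_at_boundary(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 6).tolist()
        y = rng.normal(1, 1, 7).tolist()  # n+m = 13 -> approximation path
        approx = ranksum_exact(x, y)
        exact = _ranksum_bruteforce(x, y, "two-sided")
        assert approx == pytest.approx(exact, abs=0.05)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ranksum_exact([], [1.0])


def test_end_to_end_fastq_recovery(tmp_path):
    """FASTQ emitted by the simulator, pushed through merge ->
    demultiplex -> clonotypes -> frequencies, recovers the planted
    dominant frequency within 3 binomial se."""
    freq, n_reads = 0.6, 1500
    table, truth = synthio.simulate_repertoire(
        [("t1", True, freq), ("c1", False, 0.0)],
        n_reads=n_reads, chains=("mu",), seed=21, fastq_dir=tmp_path,
    )
    merged = []
    for r1, r2 in clonality.read_fastq_pairs(
        tmp_path / "reads_R1.fastq", tmp_path / "reads_R2.fastq"
    ):
        m = merge_read_pair(r1, r2)
        if m is not None:
            merged.append(m)
    annotated, tally = demultiplex(
        merged,
        clonality.load_barcode_table(tmp_path / "barcodes.tsv"),
        clonality.load_primer_table(tmp_path / "primers.tsv"),
    )
    assert tally["no_barcode"] == 0 and tally["no_primer"] == 0
    rep = top_clone_frequencies(build_clonotypes(annotated))
    se = np.sqrt(freq * (1 - freq) / n_reads)
    for isoform in ("membrane", "secreted"):
        observed = rep.top_clones("t1", "mu", isoform)[0][1]
        assert abs(observed - freq) <= 3 * se
    assert dominant_isoform_match(rep, "t1", "mu")


def test_group_separation_mirrors_clonal_expansion():
    """Planted clonal-mu / polyclonal-gamma samples: the 5-vs-6 group
    comparison of dominant frequencies is significant for mu but not for
    gamma, >= 18/20 seeds."""
    mu_hits = gamma_miss = 0
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        samples = [(f"c{i}", False, 0.0) for i in range(5)] + [
            (f"t{i}", True, float(rng.uniform(0.5, 0.8))) for i in range(6)
        ]
        table, _ = synthio.simulate_repertoire(samples, n_reads=500, seed=seed)
        rep = top_clone_frequencies(table)
        for chain, collector in (("mu", "mu"), ("gamma", "gamma")):
            x = [
                rep.top_clones(s, chain, "membrane")[0][1]
                for s, *_ in samples[:5]
            ]
            y = [
                rep.top_clones(s, chain, "membrane")[0][1]
                for s, *_ in samples[5:]
            ]
            p = ranksum_exact(x, y)
            if chain == "mu":
                mu_hits += p < 0.05
            else:
                gamma_miss += p >= 0.05
    assert mu_hits >= 18
    assert gamma_miss >= 18
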