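"""Pileups, marker-SNP calling, allele abundances, ploidy encoding."""

import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mgmlst.profiles import (
    MISSING,
    AlleleAbundance,
    LocusPileup,
    call_marker_snps,
    encode_ploidy,
    infer_allele_abundance,
    learning_profile_to_ploidy,
    pileup_from_alignments,
    read_abundance_table,
    read_pileup_table,
    sample_to_ploidy,
    write_abundance_table,
    write_pileup_table,
    write_structure_file,
)
from mgmlst.scheme import Locus, MarkerSNP, MLSTScheme, SchemeError, StrainProfile


def pileup_with(locus, length, depth, base_at=None):
    """Uniform-depth pileup, all 'A' except overrides {pos: {base: count}}."""
    d = np.full(length, depth, dtype=np.int64)
    counts = np.zeros((length, 4), dtype=np.int64)
    counts[:, 0] = depth
    for pos, per_base in (base_at or {}).items():
        counts[pos] = 0
        for b, c in per_base.items():
            counts[pos, "ACGT".index(b)] = c
        d[pos] = sum(per_base.values())
    return LocusPileup(locus, d, counts)


TWO_LOCUS_SCHEME = MLSTScheme(
    loci=[
        Locus("x", {1: "AAAA", 2: "AATA", 3: "GAAA"}),
        Locus("y", {1: "CCCC", 2: "CTCC"}),
    ],
    default_allele={"x": 1, "y": 1},
)
X_MARKERS = [MarkerSNP("x", 2, "T", 2), MarkerSNP("x", 0, "G", 3)]
Y_MARKERS = [MarkerSNP("y", 1, "T", 2)]


# ---------------------------------------------------------------------------
# SNP calling
# ---------------------------------------------------------------------------


class TestCallMarkerSnps:
    def test_below_one_percent_is_absent_despite_many_reads(self):
        # 90 supporting reads but frequency 0.009 -> absent
        p = pileup_with("x", 4, 10000, {2: {"A": 9910, "T": 90}})
        (call,) = call_marker_snps([p], [MarkerSNP("x", 2, "T", 2)])
        assert call.count == 90 and call.frequency == pytest.approx(0.009)
        assert not call.present

    def test_three_reads_is_absent_despite_high_frequency(self):
        p = pileup_with("x", 4, 60, {2: {"A": 57, "T": 3}})
        (call,) = call_marker_snps([p], [MarkerSNP("x", 2, "T", 2)])
        assert call.frequency == pytest.approx(0.05)
        assert not call.present

    def test_fixed_marker_is_present(self):
        p = pileup_with("x", 4, 100, {2: {"T": 100}})
        (call,) = call_marker_snps([p], [MarkerSNP("x", 2, "T", 2)])
        assert call.present and call.frequency == 1.0

    def test_boundary_values_are_inclusive(self):
        p = pileup_with("x", 4, 400, {2: {"A": 396, "T": 4}})
        (call,) = call_marker_snps([p], [MarkerSNP("x", 2, "T", 2)])
        assert call.frequency == pytest.approx(0.01) and call.present

    def test_zero_depth_yields_absent_frequency_zero(self):
        p = pileup_with("x", 4, 100, {2: {}})
        (call,) = call_marker_snps([p], [MarkerSNP("x", 2, "T", 2)])
        assert call.frequency == 0.0 and not call.present

    def test_unknown_locus_is_error(self):
        p = pileup_with("x", 4, 10)
        with pytest.raises(ValueError, match="unknown locus"):
            call_marker_snps([p], [MarkerSNP("z", 0, "A", 2)])

    @given(
        count=st.integers(0, 50),
        other=st.integers(0, 500),
        f1=st.floats(0.001, 0.2),
        f2=st.floats(0.001, 0.2),
        r1=st.integers(1, 10),
        r2=st.integers(1, 10),
    )
    def test_raising_thresholds_never_makes_absent_present(
        self, count, other, f1, f2, r1, r2
    ):
        p = pileup_with("x", 4, 1, {2: {"T": count, "A": other}})
        marker = [MarkerSNP("x", 2, "T", 2)]
        lo = call_marker_snps([p], marker, min_freq=min(f1, f2), min_reads=min(r1, r2))
        hi = call_marker_snps([p], marker, min_freq=max(f1, f2), min_reads=max(r1, r2))
        assert not (hi[0].present and not lo[0].present)


# ---------------------------------------------------------------------------
# allele abundance
# ---------------------------------------------------------------------------


def calls_for(markers, freqs, depth=1000):
    """Build pileups realizing the given marker frequencies, then call."""
    by_locus = {}
    for m, f in zip(markers, freqs):
        by_locus.setdefault(m.locus, {})[m.position] = {
            m.base: round(f * depth),
            "A" if m.base != "A" else "C": depth - round(f * depth),
        }
    pileups = [pileup_with(l, 4, depth, overrides) for l, overrides in by_locus.items()]
    return call_marker_snps(pileups, markers)


class TestInferAlleleAbundance:
    def test_residual_arithmetic(self):
        # A2 at 0.30, A3 at 0.20 -> default A1 takes 0.50
        calls = calls_for(X_MARKERS, [0.30, 0.20])
        (ab,) = infer_allele_abundance(calls, X_MARKERS, TWO_LOCUS_SCHEME)
        assert ab.abundances == pytest.approx({2: 0.30, 3: 0.20, 1: 0.50})

    def test_allele_with_any_absent_marker_is_absent(self):
        markers = [MarkerSNP("x", 2, "T", 2), MarkerSNP("x", 3, "T", 2)]
        p = pileup_with("x", 4, 1000, {2: {"T": 300, "A": 700}, 3: {"A": 1000}})
        calls = call_marker_snps([p], markers)
        (ab,) = infer_allele_abundance(calls, markers, TWO_LOCUS_SCHEME)
        assert ab.abundances == pytest.approx({1: 1.0})

    def test_no_marker_present_gives_default_everything(self):
        calls = calls_for(X_MARKERS, [0.0, 0.0])
        (ab,) = infer_allele_abundance(calls, X_MARKERS, TWO_LOCUS_SCHEME)
        assert ab.abundances == pytest.approx({1: 1.0})

    def test_present_allele_takes_minimum_marker_frequency(self):
        markers = [MarkerSNP("x", 2, "T", 2), MarkerSNP("x", 3, "T", 2)]
        p = pileup_with("x", 4, 1000, {2: {"T": 300, "A": 700},
                                       3: {"T": 250, "A": 750}})
        calls = call_marker_snps([p], markers)
        (ab,) = infer_allele_abundance(calls, markers, TWO_LOCUS_SCHEME)
        assert ab.abundances[2] == pytest.approx(0.25)

    def test_mean_combination_option(self):
        markers = [MarkerSNP("x", 2, "T", 2), MarkerSNP("x", 3, "T", 2)]
        p = pileup_with("x", 4, 1000, {2: {"T": 300, "A": 700},
                                       3: {"T": 250, "A": 750}})
        calls = call_marker_snps([p], markers)
        (ab,) = infer_allele_abundance(calls, markers, TWO_LOCUS_SCHEME,
                                       combine="mean")
        assert ab.abundances[2] == pytest.approx(0.275)

    def test_small_overshoot_is_clamped_with_warning(self):
        calls = calls_for(X_MARKERS, [0.60, 0.45])  # sums to 1.05
        with pytest.warns(UserWarning, match="clamping"):
            (ab,) = infer_allele_abundance(calls, X_MARKERS, TWO_LOCUS_SCHEME)
        assert sum(ab.abundances.values()) == pytest.approx(1.0)
        assert ab.abundances[1] == 0.0

    def test_gross_overshoot_is_error(self):
        calls = calls_for(X_MARKERS, [0.70, 0.45])  # sums to 1.15
        with pytest.raises(ValueError, match="inconsistent"):
            infer_allele_abundance(calls, X_MARKERS, TWO_LOCUS_SCHEME)

    def test_abundances_always_sum_to_one(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            f = rng.uniform(0, 0.45, size=2)
            calls = calls_for(X_MARKERS, list(f))
            (ab,) = infer_allele_abundance(calls, X_MARKERS, TWO_LOCUS_SCHEME)
            assert sum(ab.abundances.values()) == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# ploidy encoding
# ---------------------------------------------------------------------------


class TestEncodePloidy:
    def test_ten_percent_gives_ten_copies(self):
        vec = encode_ploidy(AlleleAbundance("x", {5: 0.10, 2: 0.90}))
        assert (vec == 5).sum() == 10 and (vec == 2).sum() == 90

    def test_101_repair_decrements_lowest_id_of_tied_top(self):
        vec = encode_ploidy(AlleleAbundance("x", {1: 0.335, 2: 0.335, 3: 0.33}))
        assert len(vec) == 100
        assert (vec == 1).sum() == 33 and (vec == 2).sum() == 34
        assert (vec == 3).sum() == 33

    def test_99_repair_inserts_missing(self):
        vec = encode_ploidy(AlleleAbundance("x", {1: 0.333, 2: 0.333, 3: 0.334}))
        assert len(vec) == 100 and (vec == MISSING).sum() == 1

    def test_single_allele_gives_full_ploidy(self):
        vec = encode_ploidy(AlleleAbundance("x", {7: 1.0}))
        assert (vec == 7).sum() == 100

    def test_largest_remainder_fallback(self):
        # seven alleles at 1/7 round to 14 each = 98: off by two
        ab = AlleleAbundance("x", {i: 1 / 7 for i in range(1, 8)})
        vec = encode_ploidy(ab)
        assert len(vec) == 100 and MISSING not in vec
        counts = {i: (vec == i).sum() for i in range(1, 8)}
        assert sorted(counts.values()) == [14, 14, 14, 14, 14, 15, 15]

    def test_negative_abundance_is_error(self):
        ab = AlleleAbundance.__new__(AlleleAbundance)
        ab.locus, ab.abundances = "x", {1: -0.1, 2: 1.1}
        with pytest.raises(ValueError, match="negative"):
            encode_ploidy(ab)

    @given(
        weights=st.lists(st.floats(0.001, 1.0), min_size=1, max_size=12),
        ploidy=st.sampled_from([10, 100, 101]),
    )
    def test_output_length_is_exactly_ploidy_for_any_simplex(self, weights, ploidy):
        w = np.array(weights) / sum(weights)
        ab = AlleleAbundance("x", dict(enumerate(w, start=1)))
        assert len(encode_ploidy(ab, ploidy=ploidy)) == ploidy


class TestLearningProfileToPloidy:
    def test_expands_to_identical_copies(self, synthetic):
        scheme, curated = synthetic
        prof = learning_profile_to_ploidy(curated[0], scheme)
        assert prof.popflag and prof.group == curated[0].group
        for locus in scheme.locus_names:
            assert prof.ploidy == 100
            assert np.all(prof.copies[locus] == curated[0].profile[locus])

    def test_whole_learning_set(self, synthetic):
        scheme, curated = synthetic
        profs = [learning_profile_to_ploidy(sp, scheme) for sp in curated]
        assert len(profs) == len(curated) and all(p.popflag for p in profs)

    def test_incomplete_profile_is_error(self, synthetic):
        scheme, _ = synthetic
        sp = StrainProfile("bad", "RT1", {"locus1": 1})
        with pytest.raises(SchemeError, match="no allele for locus"):
            learning_profile_to_ploidy(sp, scheme)


# ---------------------------------------------------------------------------
# pileups from alignments
# ---------------------------------------------------------------------------


def write_sam(path, reads, contigs={"ref": 20}):
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    lines += [f"@SQ\tSN:{c}\tLN:{n}" for c, n in contigs.items()]
    for name, flag, contig, pos1, mapq, cigar, seq in reads:
        lines.append(
            f"{name}\t{flag}\t{contig}\t{pos1}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t*"
        )
    path.write_text("\n".join(lines) + "\n")


class TestPileupFromAlignments:
    def test_identical_reads_spanning_locus(self, tmp_path):
        sam = tmp_path / "a.sam"
        write_sam(sam, [(f"r{i}", 0, "ref", 5, 60, "4M", "ACGT") for i in range(10)])
        (p,) = pileup_from_alignments(sam, {"x": ("ref", 4, 8)})
        assert np.all(p.depth == 10)
        assert np.all(p.base_counts[:, :] == np.eye(4, dtype=int)[[0, 1, 2, 3]] * 10)

    def test_half_covered_locus_has_zero_depth_elsewhere(self, tmp_path):
        sam = tmp_path / "a.sam"
        write_sam(sam, [("r0", 0, "ref", 5, 60, "2M", "AC")])
        (p,) = pileup_from_alignments(sam, {"x": ("ref", 4, 8)})
        assert list(p.depth) == [1, 1, 0, 0]

    def test_mapq_floor_excludes_reads(self, tmp_path):
        sam = tmp_path / "a.sam"
        write_sam(sam, [("r0", 0, "ref", 5, 3, "4M", "ACGT"),
                        ("r1", 0, "ref", 5, 60, "4M", "ACGT")])
        (p,) = pileup_from_alignments(sam, {"x": ("ref", 4, 8)}, min_mapq=10)
        assert np.all(p.depth == 1)

    def test_empty_alignment_warns_and_zeroes(self, tmp_path):
        sam = tmp_path / "a.sam"
        write_sam(sam, [])
        with pytest.warns(UserWarning, match="no aligned reads"):
            (p,) = pileup_from_alignments(sam, {"x": ("ref", 4, 8)})
        assert np.all(p.depth == 0)

    def test_interval_outside_reference_is_error(self, tmp_path):
        sam = tmp_path / "a.sam"
        write_sam(sam, [])
        with pytest.raises(ValueError, match="outside"):
            pileup_from_alignments(sam, {"x": ("ref", 10, 30)})


# ---------------------------------------------------------------------------
# table round-trips and STRUCTURE export
# ---------------------------------------------------------------------------


class TestTables:
    def test_pileup_table_roundtrip(self, tmp_path):
        p = pileup_with("x", 4, 50, {1: {"T": 30, "G": 20}})
        write_pileup_table([p], tmp_path / "p.tsv")
        (back,) = read_pileup_table(tmp_path / "p.tsv")
        assert back.locus == "x"
        assert np.array_equal(back.depth, p.depth)
        assert np.array_equal(back.base_counts, p.base_counts)

    def test_abundance_table_roundtrip(self, tmp_path):
        ab = [AlleleAbundance("x", {1: 0.5, 2: 0.5}), AlleleAbundance("y", {1: 1.0})]
        write_abundance_table("s1", ab, tmp_path / "a.tsv")
        back = read_abundance_table(tmp_path / "a.tsv")
        assert list(back) == ["s1"]
        assert back["s1"][0].abundances == pytest.approx({1: 0.5, 2: 0.5})

    def test_structure_file_format(self, synthetic, tmp_path):
        scheme, curated = synthetic
        prof = learning_profile_to_ploidy(curated[0], scheme)
        sample = sample_to_ploidy(
            "s", [AlleleAbundance(l, {1: 1.0}) for l in scheme.locus_names], ploidy=100
        )
        out = tmp_path / "structure.tsv"
        write_structure_file([prof, sample], scheme.locus_names, out)
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == ["label", "pop", "popflag"] + scheme.locus_names
        assert len(lines) == 1 + 200
        first = lines[1].split("\t")
        assert first[:3] == [curated[0].strain, "1", "1"]
        unlabeled = lines[101].split("\t")
        assert unlabeled[:3] == ["s", "0", "0"]
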