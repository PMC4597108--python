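"""PWM construction, scanning, exact score distributions, composite sites,
region classification, and ZOOPS-EM discovery."""

import itertools

import numpy as np
import pytest

from cobindscan.intervals import Interval, PeakSet, ValidationError
from cobindscan.motifs import (
    PWM,
    MotifMatch,
    detect_composite,
    classify_regions,
    discover_motif_zoops_em,
    pwm_from_counts,
    read_matrix_tsv,
    read_meme_minimal,
    reverse_complement,
    scan,
    score_distribution,
    threshold_for_pvalue,
    write_meme_minimal,
)
from cobindscan.simulate import (
    MEIS_CONSENSUS,
    SELEX_CONSENSUS,
    build_hybrid_consensus,
    consensus_pwm,
)


def brute_force_scan(pwm, seq, thr):
    """Independent per-window rescoring oracle (both strands)."""
    out = []
    w = pwm.width
    for strand in "+-":
        for i in range(len(seq) - w + 1):
            win = seq[i : i + w]
            if "N" in win:
                continue
            tgt = win if strand == "+" else reverse_complement(win)
            sc = sum(pwm.log_odds[k, "ACGT".index(b)] for k, b in enumerate(tgt))
            if sc >= thr - 1e-9:
                out.append((i, strand, round(sc, 9)))
    return sorted(out)


def enumerate_score_pmf(pwm, granularity=1e-3):
    """Weighted enumeration of all 4^w windows on the rounded score grid."""
    g = granularity
    q = np.rint(pwm.log_odds / g).astype(int)
    masses: dict[int, float] = {}
    bg = pwm.background
    for win in itertools.product(range(4), repeat=pwm.width):
        k = int(sum(q[i, b] for i, b in enumerate(win)))
        p = float(np.prod([bg[b] for b in win]))
        masses[k] = masses.get(k, 0.0) + p
    return masses


class TestPwmConstruction:
    def test_pseudocount_formula(self):
        pwm = pwm_from_counts(np.array([[10, 0, 0, 0]] * 4), pseudocount=1.0)
        assert pwm.probs[0, 0] == pytest.approx(10.25 / 11)
        assert pwm.probs[0, 1] == pytest.approx(0.25 / 11)

    def test_uniform_counts_give_zero_log_odds(self):
        pwm = pwm_from_counts(np.full((5, 4), 7), pseudocount=0.1)
        assert np.allclose(pwm.log_odds, 0)

    def test_rows_normalized(self, rng):
        counts = rng.integers(0, 50, (6, 4))
        pwm = pwm_from_counts(counts)
        assert np.allclose(pwm.probs.sum(axis=1), 1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            pwm_from_counts(np.array([[1, -1, 0, 0]] * 4))

    def test_consensus_and_rc(self):
        pwm = consensus_pwm("ACGTAA", "m")
        assert pwm.consensus == "ACGTAA"
        assert pwm.reverse_complement().consensus == "TTACGT"


class TestScan:
    def test_consensus_attains_max_score(self):
        pwm = consensus_pwm("ACGTAC", "m")
        matches = scan(pwm, "ACGTAC", pwm.max_score)
        assert len(matches) == 1
        m = matches[0]
        assert (m.start, m.end, m.strand) == (0, 6, "+")
        assert m.score == pytest.approx(pwm.max_score)

    def test_reverse_complement_match(self):
        pwm = consensus_pwm("ACGTAC", "m")
        matches = scan(pwm, reverse_complement("ACGTAC"), pwm.max_score)
        assert len(matches) == 1 and matches[0].strand == "-"

    def test_forward_only_skips_reverse(self):
        pwm = consensus_pwm("ACGTAC", "m")
        assert scan(pwm, reverse_complement("ACGTAC"), pwm.max_score,
                    strands="forward") == []

    def test_short_sequence_empty(self):
        pwm = consensus_pwm("ACGTAC", "m")
        assert scan(pwm, "ACG", 0.0) == []

    def test_n_windows_skipped(self):
        pwm = consensus_pwm("ACGTAC", "m")
        assert scan(pwm, "ACGNAC", pwm.min_score) == []

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            w = int(rng.integers(5, 9))
            pwm = pwm_from_counts(rng.integers(0, 20, (w, 4)), motif_id="t")
            seq = "".join(rng.choice(list("ACGTN"), p=[0.24] * 4 + [0.04])
                          for _ in range(500))
            thr = score_distribution(pwm).threshold_for_pvalue(0.01)
            got = sorted((m.start, m.strand, round(m.score, 9))
                         for m in scan(pwm, seq, thr))
            assert got == brute_force_scan(pwm, seq, thr)

    def test_reverse_complement_symmetry(self, rng):
        pwm = pwm_from_counts(rng.integers(0, 20, (6, 4)), motif_id="t")
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        thr = score_distribution(pwm).threshold_for_pvalue(0.01)
        fwd = {(m.start, m.strand) for m in scan(pwm, seq, thr)}
        rev = {
            (len(seq) - m.end, {"+": "-", "-": "+"}[m.strand])
            for m in scan(pwm, reverse_complement(seq), thr)
        }
        assert fwd == rev


class TestScoreDistribution:
    def test_single_informative_position_two_point(self):
        # three uniform rows contribute score 0; the remaining row has
        # probs (1/2, 1/6, 1/6, 1/6) -> masses 1/4 and 3/4 at two scores
        probs = np.vstack([[0.5, 1 / 6, 1 / 6, 1 / 6], np.full((3, 4), 0.25)])
        dist = score_distribution(PWM("m", probs))
        nz = dist.pmf[dist.pmf > 0]
        assert len(nz) == 2
        assert sorted(nz) == pytest.approx([0.25, 0.75])

    def test_mass_sums_to_one(self, rng):
        pwm = pwm_from_counts(rng.integers(0, 30, (7, 4)))
        assert score_distribution(pwm).pmf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_enumeration_w5(self, rng):
        pwm = pwm_from_counts(rng.integers(0, 20, (5, 4)))
        dist = score_distribution(pwm)
        want = enumerate_score_pmf(pwm)
        got = {dist.offset + i: p for i, p in enumerate(dist.pmf) if p > 0}
        keys = set(want) | set(got)
        tv = 0.5 * sum(abs(want.get(k, 0) - got.get(k, 0)) for k in keys)
        assert tv < 1e-9

    def test_threshold_p1_is_min_score(self, rng):
        pwm = pwm_from_counts(rng.integers(0, 20, (5, 4)))
        dist = score_distribution(pwm)
        thr = threshold_for_pvalue(dist, 1.0)
        assert thr == pytest.approx(dist.scores[np.nonzero(dist.pmf)[0][0]])

    def test_tiny_p_above_max_score(self):
        pwm = consensus_pwm("ACGTA", "m", p_major=0.7)
        dist = score_distribution(pwm)
        thr = dist.threshold_for_pvalue(1e-12)
        assert thr > pwm.max_score
        assert scan(pwm, "ACGTA", thr) == []

    def test_threshold_is_largest_valid_tail(self, rng):
        pwm = pwm_from_counts(rng.integers(0, 20, (5, 4)))
        dist = score_distribution(pwm)
        masses = enumerate_score_pmf(pwm)
        g = dist.granularity
        for p in (0.05, 0.01, 1e-3):
            thr = dist.threshold_for_pvalue(p)
            if thr == float("inf"):
                # unattainable tail: even the single best outcome exceeds p
                assert masses[max(masses)] > p
                continue
            k_thr = int(round(thr / g))
            tail = sum(v for k, v in masses.items() if k >= k_thr)
            assert tail <= p + 1e-12
            # one grid step lower must exceed p (largest qualifying tail)
            below = sum(
                v for k, v in masses.items()
                if k >= max(k for k in masses if k < k_thr)
            )
            assert below > p


class TestCompositeSites:
    def _match(self, start, end, chrom="chr1", mid="m"):
        return MotifMatch(mid, chrom, start, end, "+", 5.0)

    def test_overlap_geometry(self):
        sites = detect_composite(
            [self._match(10, 17)], [self._match(13, 19)], 1)
        assert len(sites) == 1
        assert sites[0].overlap_bp == 4 and sites[0].offset == 3

    def test_disjoint_empty(self):
        assert detect_composite([self._match(10, 17)], [self._match(30, 36)], 1) == []

    def test_min_overlap_validation(self):
        with pytest.raises(ValidationError):
            detect_composite([], [], min_overlap_bp=0)

    def test_matches_all_pairs_filter(self, rng):
        def rand_matches(n):
            out = []
            for _ in range(n):
                s = int(rng.integers(0, 200))
                out.append(self._match(s, s + int(rng.integers(5, 12))))
            return out

        a, b = rand_matches(30), rand_matches(30)
        got = {(s.match_a.start, s.match_b.start) for s in
               detect_composite(a, b, 2, max_abs_offset=8)}
        want = set()
        for ma in a:
            for mb in b:
                ov = min(ma.end, mb.end) - max(ma.start, mb.start)
                if ov >= 2 and abs(mb.start - ma.start) <= 8:
                    want.add((ma.start, mb.start))
        assert got == want


class TestClassifyRegions:
    SELEX = consensus_pwm(SELEX_CONSENSUS, "selex")
    DENOVO = consensus_pwm(build_hybrid_consensus(), "denovo")

    def _region_with(self, rng, planted):
        """A 200-bp chromosome with `planted` substituted at the summit."""
        seq = list("ACGT"[i] for i in rng.integers(0, 4, 200))
        summit = 100
        for motif, rel in planted:
            seq[summit + rel : summit + rel + len(motif)] = motif
        return "".join(seq), Interval("chrT", 50, 150, name="r", summit=50)

    def test_planted_classes(self, rng):
        hybrid = build_hybrid_consensus()
        cases = [
            ([(hybrid, -5)], "denovo_only"),
            ([(SELEX_CONSENSUS, -3)], "selex_only"),
            ([(hybrid, -5), (SELEX_CONSENSUS, -20)], "both"),
            ([], "neither"),
        ]
        for planted, expect in cases:
            seq, region = self._region_with(rng, planted)
            classes, summary = classify_regions(
                PeakSet([region]), {"chrT": seq}, self.SELEX, self.DENOVO, k=25
            )
            assert classes[0].motif_class == expect, (planted, expect)

    def test_pure_background_tiny_threshold_neither(self, rng):
        seq, region = self._region_with(rng, [])
        classes, _ = classify_regions(
            PeakSet([region]), {"chrT": seq}, self.SELEX, self.DENOVO,
            k=25, p_threshold=1e-12,
        )
        assert classes[0].motif_class == "neither"

    def test_classes_exhaustive_and_fractions_sum(self, sim_dataset):
        from cobindscan.intervals import read_bed, read_chrom_sizes
        from cobindscan.motifs import read_fasta

        cfg, paths, truth = sim_dataset
        regions = read_bed(paths["peaks_a"], "narrowPeak")
        classes, summary = classify_regions(
            regions, read_fasta(paths["genome_fasta"]),
            cfg.pwms()["selex"], cfg.pwms()["denovo"],
            genome=read_chrom_sizes(paths["chrom_sizes"]),
        )
        assert len(classes) == len(regions)
        n = (summary["n_denovo_only"] + summary["n_selex_only"]
             + summary["n_both"] + summary["n_neither"])
        assert n == len(regions)

    def test_missing_chromosome_names_region(self):
        region = Interval("chrX", 50, 150, summit=50)
        with pytest.raises(ValidationError, match="chrX"):
            classify_regions(PeakSet([region]), {"chrT": "A" * 200},
                             self.SELEX, self.DENOVO)


class TestZoopsEm:
    def test_single_window_forced(self):
        seq = "ACGTACGT"
        pwm = discover_motif_zoops_em([seq], width=8, n_starts=1, seed=0,
                                      pseudocount=0.1)
        assert pwm.consensus == seq
        # smoothed indicator: dominant prob close to (w + pc*bg)/(w + pc)
        assert pwm.probs.max(axis=1).min() > 0.9

    def test_planted_consensus_recovered(self, rng):
        planted = "TGACAG"
        seqs = []
        for _ in range(200):
            s = "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
            off = int(rng.integers(0, 45))
            seqs.append(s[:off] + planted + s[off + 6 :])
        pwm = discover_motif_zoops_em(seqs, 6, n_starts=5, seed=1)
        assert pwm.consensus == planted

    def test_background_yields_lower_information_content(self, rng):
        planted = "TGACAG"
        sig, noise = [], []
        for _ in range(100):
            s = "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
            off = int(rng.integers(0, 45))
            sig.append(s[:off] + planted + s[off + 6 :])
            noise.append("".join("ACGT"[i] for i in rng.integers(0, 4, 50)))
        ic_sig = discover_motif_zoops_em(sig, 6, n_starts=3, seed=2).information_content
        ic_noise = discover_motif_zoops_em(noise, 6, n_starts=3, seed=2).information_content
        assert ic_noise < ic_sig

    def test_width_validation(self):
        with pytest.raises(ValidationError):
            discover_motif_zoops_em(["ACGT"], width=5)

    def test_same_seed_bit_identical(self, rng):
        seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 30))
                for _ in range(20)]
        a = discover_motif_zoops_em(seqs, 5, n_starts=2, seed=7)
        b = discover_motif_zoops_em(seqs, 5, n_starts=2, seed=7)
        assert np.array_equal(a.probs, b.probs)


class TestPwmIO:
    def test_meme_minimal_round_trip(self, tmp_path, rng):
        pwms = [pwm_from_counts(rng.integers(0, 30, (6, 4)), motif_id="m1"),
                consensus_pwm("ACGTACG", "m2")]
        path = tmp_path / "motifs.meme"
        write_meme_minimal(pwms, path)
        back = read_meme_minimal(path)
        assert [p.motif_id for p in back] == ["m1", "m2"]
        for orig, rt in zip(pwms, back):
            assert np.allclose(orig.probs, rt.probs, atol=1e-9)

    def test_matrix_tsv_counts_and_probs(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("A C G T\n10 0 0 0\n0 10 0 0\n0 0 10 0\n0 0 0 10\n")
        pwm = read_matrix_tsv(p, motif_id="m", pseudocount=1.0)
        assert pwm.consensus == "ACGT"
        assert pwm.probs[0, 0] == pytest.approx(10.25 / 11)
        q = tmp_path / "probs.tsv"
        q.write_text("0.7 0.1 0.1 0.1\n" * 4)
        assert read_matrix_tsv(q, motif_id="p").probs[0, 0] == pytest.approx(0.7)
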