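"""Electronic digestion, amplicon prediction and the QUAluome census."""

import numpy as np
import pytest

from _oracle import naive_amplifiable_anchors, naive_motif_positions
from qualu import (
    ALU_CONSENSUS,
    MethylationState,
    MiniGenomeSpec,
    RepeatFeature,
    default_scheme,
    digest,
    expected_puma,
    find_sites,
    make_minigenome,
    predict_amplicons,
    quameome_census,
    simulate_methylation,
)
from qualu.virtual_qpcr import PrimerScheme, _check_l1_amplicon


def random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3], size=n))


def methylate_all(sites):
    meth = MethylationState()
    for s in sites:
        meth.set_beta(s.contig, s.cut_position, 1.0)
    return meth


class TestFindSites:
    def test_cut_position_and_context_flags(self):
        (site,) = find_sites("AAACCGGT")
        assert site.site_start == 3
        assert site.cut_position == 4  # AAAC | CGGT
        assert not site.in_aacccgg_context

        (site,) = find_sites("TAACCCGGT")
        assert site.in_aacccgg_context and site.context_forward

        (site,) = find_sites("TCCGGGTTA")  # AACCCGG on the reverse strand
        assert site.in_aacccgg_context and site.context_reverse

    def test_matches_naive_scan_on_random_sequence(self):
        seq = random_seq(10_000, seed=5)
        sites = find_sites(seq)
        expected = [i for i, _ in naive_motif_positions(seq, "CCGG", False)]
        assert [s.site_start for s in sites] == expected
        for s in sites:
            assert seq[s.site_start : s.site_start + 4] == "CCGG"


class TestDigest:
    def test_mspi_cuts_every_site(self):
        frags = digest("AAACCGGTTT", "MspI")
        assert frags["seq"] == [(0, 4), (4, 10)]

    def test_hpaii_blocked_by_methylation(self):
        sites = find_sites("AAACCGGTTT")
        meth = methylate_all(sites)
        assert digest("AAACCGGTTT", "HpaII", meth)["seq"] == [(0, 10)]
        assert digest("AAACCGGTTT", "MspI", meth)["seq"] == [(0, 4), (4, 10)]

    def test_unknown_enzyme_rejected(self):
        with pytest.raises(ValueError, match="enzyme"):
            digest("ACGT", "EcoRI")

    def test_hpaii_cuts_subset_and_fragments_partition(self):
        seq = random_seq(20_000, seed=11)
        sites = find_sites(seq)
        meth = simulate_methylation(sites, p_unmethylated=0.5, seed=2)
        hpa = digest(seq, "HpaII", meth)["seq"]
        msp = digest(seq, "MspI", meth)["seq"]
        hpa_cuts = {f[0] for f in hpa[1:]}
        msp_cuts = {f[0] for f in msp[1:]}
        assert hpa_cuts <= msp_cuts
        for frags in (hpa, msp):
            assert frags[0][0] == 0 and frags[-1][1] == len(seq)
            assert all(a[1] == b[0] for a, b in zip(frags, frags[1:]))
            assert sum(e - s for s, e in frags) == len(seq)


def plant_single_alu(flank=100, seed=21):
    """One perfect consensus copy on a CCGG-free random background."""
    while True:
        bg_left, bg_right = random_seq(flank, seed), random_seq(flank, seed + 1)
        seq = bg_left + ALU_CONSENSUS + bg_right
        if seq.count("CCGG") == ALU_CONSENSUS.count("CCGG"):
            break
        seed += 2
    feat = RepeatFeature("c", flank, flank + len(ALU_CONSENSUS), "+",
                         "AluYsim", "Alu", "SINE")
    return {"c": seq}, feat


class TestPredictAmplicons:
    def test_perfect_element_yields_one_amplicon(self, scheme):
        genome, feat = plant_single_alu()
        amps = predict_amplicons(genome, [feat], scheme, "HpaII")
        assert len(amps) == 1
        (a,) = amps
        assert a.element == feat and a.strand == "+"
        assert scheme.amplicon_min <= a.length <= scheme.amplicon_max
        assert a.anchored_site.in_aacccgg_context
        assert feat.start <= a.anchored_site.site_start < feat.end

    def test_methylation_blocks_hpaii_but_not_mspi(self, scheme):
        genome, feat = plant_single_alu()
        meth = methylate_all(find_sites(genome))
        assert predict_amplicons(genome, [feat], scheme, "HpaII", meth) == []
        assert len(predict_amplicons(genome, [feat], scheme, "MspI", meth)) == 1

    def test_matches_exhaustive_placement_oracle(self, scheme, mini_genome):
        spec, genome, ann = mini_genome
        amps = predict_amplicons(genome, ann["alu"], scheme, "MspI")
        got = {(a.anchored_site.site_start, a.strand, a.element) for a in amps}
        expected = naive_amplifiable_anchors(
            genome[spec.contig_name], spec.contig_name, ann["alu"], scheme
        )
        assert got == expected

    def test_hpaii_amplicons_subset_of_mspi(self, scheme, mini_genome, mini_sites):
        spec, genome, ann = mini_genome
        meth = simulate_methylation(mini_sites, 0.3, seed=4)
        key = lambda a: (a.anchored_site.site_start, a.strand)
        hpa = {key(a) for a in predict_amplicons(genome, ann["alu"], scheme, "HpaII", meth)}
        msp = {key(a) for a in predict_amplicons(genome, ann["alu"], scheme, "MspI", meth)}
        assert hpa <= msp
        unmeth = predict_amplicons(genome, ann["alu"], scheme, "HpaII")
        assert {key(a) for a in unmeth} == msp

    def test_zero_mismatch_amplicons_subset_of_one_mismatch(self, mini_genome):
        spec, genome, ann = mini_genome
        strict = default_scheme(max_mismatches=0)
        loose = default_scheme(max_mismatches=1)
        key = lambda a: (a.anchored_site.site_start, a.strand)
        s0 = {key(a) for a in predict_amplicons(genome, ann["alu"], strict)}
        s1 = {key(a) for a in predict_amplicons(genome, ann["alu"], loose)}
        assert s0 <= s1

    def test_reverse_strand_element_amplifies(self, scheme):
        genome, feat = plant_single_alu()
        from qualu import revcomp

        flipped = {"c": revcomp(genome["c"])}
        L = len(genome["c"])
        feat_r = RepeatFeature("c", L - feat.end, L - feat.start, "-",
                               "AluYsim", "Alu", "SINE")
        amps = predict_amplicons(flipped, [feat_r], scheme, "MspI")
        assert len(amps) == 1 and amps[0].strand == "-"


class TestQuameome:
    def test_distinct_element_count(self, scheme):
        genome, feat = plant_single_alu()
        amps = predict_amplicons(genome, [feat], scheme)
        summary = quameome_census(amps * 3, [feat] * 2)
        assert summary.n_elements == 1
        assert summary.fraction_of_aluome == pytest.approx(0.5)

    def test_young_subfamilies_overrepresented(self, scheme):
        spec = MiniGenomeSpec(n_alu=150, n_line=0, n_cgi=0, contig_length=80_000,
                              alu_divergence_range=(0.0, 0.3), seed=13)
        genome, ann = make_minigenome(spec)
        amps = predict_amplicons(genome, ann["alu"], scheme)
        summary = quameome_census(amps, ann["alu"])
        aluome = {name: sum(f.rep_name == name for f in ann["alu"])
                  for name in ("AluYsim", "AluJsim")}
        share = {
            name: summary.subfamily_counts.get(name, 0) / aluome[name]
            for name in aluome
        }
        assert share["AluYsim"] > share["AluJsim"]


class TestExpectedPuma:
    def test_extremes(self, scheme, mini_genome, mini_sites):
        spec, genome, ann = mini_genome
        assert expected_puma(genome, ann["alu"], scheme) == 100.0
        meth = methylate_all(mini_sites)
        assert expected_puma(genome, ann["alu"], scheme, meth) == 0.0

    def test_monotone_in_methylation(self, scheme, mini_genome, mini_sites):
        spec, genome, ann = mini_genome
        meth = MethylationState()
        previous = expected_puma(genome, ann["alu"], scheme, meth, sites=mini_sites)
        for site in mini_sites:
            meth.set_beta(site.contig, site.cut_position, 1.0)
            now = expected_puma(genome, ann["alu"], scheme, meth, sites=mini_sites)
            assert now <= previous
            previous = now

    def test_recovers_binomial_unmethylated_fraction(self, scheme):
        spec = MiniGenomeSpec(n_alu=1200, n_line=0, n_cgi=0, contig_length=500_000,
                              alu_divergence_range=(0.0, 0.01), seed=17)
        genome, ann = make_minigenome(spec)
        sites = find_sites(genome)
        n_amplifiable = len(predict_amplicons(genome, ann["alu"], scheme, sites=sites))
        assert n_amplifiable >= 1000
        p = 0.10
        meth = simulate_methylation(sites, p, seed=23)
        puma = expected_puma(genome, ann["alu"], scheme, meth, sites=sites)
        se = 100 * (p * (1 - p) / n_amplifiable) ** 0.5
        assert abs(puma - 100 * p) < 3 * se

    def test_no_amplifiable_products_is_an_error(self, scheme):
        with pytest.raises(ValueError, match="MspI"):
            expected_puma({"c": "ACGTACGT"}, [], scheme)


def test_l1_amplicon_with_ccgg_warns():
    from qualu import L1_CONSENSUS

    # primers straddling an artificial CCGG would break normalization
    bad = PrimerScheme(
        adaptor_sequence="GACTCAGTACGATTGGAATC",
        alu_primer="A" * 20,
        l1pa_forward=L1_CONSENSUS[0:20],
        l1pa_reverse="TTTTGGGGTTTTGGGGTTTT",
    )
    _check_l1_amplicon(bad)  # CCGG-free primers off-consensus: silently fine
    with pytest.warns(UserWarning, match="CCGG"):
        _check_l1_amplicon(
            PrimerScheme(
                adaptor_sequence="GACTCAGTACGATTGGAATC",
                alu_primer="A" * 20,
                l1pa_forward="TTTTAAAACCGGAAAATTTT",  # carries a CCGG site
                l1pa_reverse="TTTTGGGGTTTTGGGGTTTT",
            )
        )
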