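import numpy as np
import pytest

import asprime as ap
from asprime.insilico_pcr import BindingModel, virtual_gel

import oracles


def mkprimer(core, name="p", orientation="forward", tail=""):
    return ap.Primer(name=name, core=core, tail=tail, orientation=orientation)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestFindBindingSites:
    def test_template_equal_to_core_single_plus_site(self):
        p = mkprimer("ACGTTGCAACGTTGCAAT")
        sites = ap.find_binding_sites(ap.SeqRecord("t", p.core), p)
        assert len(sites) == 1
        s = sites[0]
        assert (s.strand, s.start, s.end, s.mismatch_total) == ("+", 0, 18, 0)

    def test_reverse_primer_site_on_minus_strand(self):
        rng = np.random.default_rng(0)
        template = random_seq(rng, 50) + ap.revcomp(ap.HCO_2198) + random_seq(rng, 50)
        p = mkprimer(ap.HCO_2198, name="HCO", orientation="reverse")
        sites = ap.find_binding_sites(ap.SeqRecord("t", template), p)
        assert [(s.strand, s.start) for s in sites] == [("-", 50)]

    def test_tail_excluded_from_matching(self):
        core = "GATTTGGAAACTGATTACTG"
        tailed = mkprimer(core, tail="GCGGGCAGGGCGGCGGGGGCGGGGCC")
        sites = ap.find_binding_sites(ap.SeqRecord("t", core), tailed)
        assert len(sites) == 1 and sites[0].mismatch_total == 0

    def test_n_matches_count_half_rounded_up(self):
        core = "ACGTTGCAACGTTGCAATGG"
        for n_count, extra in ((1, 1), (2, 1), (3, 2)):
            t = "N" * n_count + core[n_count:]
            sites = ap.find_binding_sites(
                ap.SeqRecord("t", t), mkprimer(core), BindingModel(max_total_mismatches=3)
            )
            assert sites and sites[0].mismatch_total == extra

    def test_three_prime_terminal_mismatch_blocks_binding(self):
        core = "ACGTTGCAACGTTGCAATGG"
        t = core[:-1] + "C"  # flip the 3'-terminal base
        assert ap.find_binding_sites(ap.SeqRecord("t", t), mkprimer(core)) == []
        relaxed = BindingModel(window_mismatches_allowed=1)
        assert len(ap.find_binding_sites(ap.SeqRecord("t", t), mkprimer(core), relaxed)) == 1

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            template = random_seq(rng, int(rng.integers(60, 400)))
            core_len = int(rng.integers(15, 27))
            # half the time embed a mutated copy so sites actually occur
            core = random_seq(rng, core_len)
            if rng.random() < 0.7:
                pos = int(rng.integers(0, len(template) - core_len))
                embedded = list(core)
                for j in rng.choice(core_len, rng.integers(0, 4), replace=False):
                    embedded[j] = str(rng.choice(list("ACGT")))
                template = template[:pos] + "".join(embedded) + template[pos + core_len :]
            if rng.random() < 0.3:  # sprinkle Ns
                t = list(template)
                for j in rng.choice(len(t), 3, replace=False):
                    t[j] = "N"
                template = "".join(t)
            model = BindingModel(
                max_total_mismatches=int(rng.integers(0, 5)),
                three_prime_window=int(rng.integers(0, 4)),
                window_mismatches_allowed=int(rng.integers(0, 2)),
            )
            got = {
                (s.strand, s.start, s.mismatch_total, s.mismatch_positions)
                for s in ap.find_binding_sites(ap.SeqRecord("t", template), mkprimer(core), model)
            }
            want = oracles.brute_sites(template, core, model)
            assert got == want

    def test_relaxing_thresholds_yields_superset(self):
        rng = np.random.default_rng(31)
        template = random_seq(rng, 300)
        core = template[100:120]
        rec = ap.SeqRecord("t", template)
        p = mkprimer(core)
        base = {(s.strand, s.start) for s in ap.find_binding_sites(rec, p, BindingModel())}
        for relaxed in (
            BindingModel(max_total_mismatches=5),
            BindingModel(window_mismatches_allowed=2),
            BindingModel(three_prime_window=0),
        ):
            more = {(s.strand, s.start) for s in ap.find_binding_sites(rec, p, relaxed)}
            assert base <= more


class TestSimulatePcr:
    def test_span_plus_tail_arithmetic(self):
        rng = np.random.default_rng(3)
        fwd_core = random_seq(rng, 20)
        rev_core = random_seq(rng, 22)
        middle = random_seq(rng, 170)
        template = fwd_core + middle + ap.revcomp(rev_core)
        fwd = mkprimer(fwd_core, "f", tail="GC" * 13)
        rev = mkprimer(rev_core, "r", orientation="reverse")
        amps = ap.simulate_pcr(ap.SeqRecord("t", template), [fwd, rev])
        bands = [a for a in amps if not a.nonspecific]
        assert len(bands) == 1
        a = bands[0]
        assert a.genomic_span == 212
        assert a.product_len == 238
        assert a.product_len - a.genomic_span == len(fwd.tail) + len(rev.tail)

    def test_no_forward_site_means_no_products(self):
        rng = np.random.default_rng(4)
        rev_core = random_seq(rng, 20)
        template = random_seq(rng, 150) + ap.revcomp(rev_core)
        fwd = mkprimer(random_seq(rng, 20), "f")
        rev = mkprimer(rev_core, "r", orientation="reverse")
        amps = ap.simulate_pcr(ap.SeqRecord("t", template), [fwd, rev])
        assert amps == []

    def test_reverse_complement_template_preserves_product_multiset(self, packaged_panel, packaged_refs):
        primers = list(packaged_panel.forward_primers) + [packaged_panel.reverse_primer]
        for rec in packaged_refs:
            fwd = [a.product_len for a in ap.simulate_pcr(rec, primers)]
            flipped = ap.SeqRecord(rec.id, ap.revcomp(rec.seq))
            rev = [a.product_len for a in ap.simulate_pcr(flipped, primers)]
            assert sorted(fwd) == sorted(rev)

    def test_matches_bruteforce_products(self, packaged_panel):
        rng = np.random.default_rng(11)
        primers = list(packaged_panel.forward_primers) + [packaged_panel.reverse_primer]
        refs = ap.synthetic_reference_templates(packaged_panel)
        model = BindingModel()
        for rec in refs:
            got = [a.product_len for a in ap.simulate_pcr(rec, primers, model)]
            assert got == oracles.brute_products(rec.seq, primers, model)
        # and on random templates with embedded sites
        for _ in range(10):
            t = random_seq(rng, 500)
            p = primers[int(rng.integers(0, len(primers)))]
            pos = int(rng.integers(0, 400))
            t = t[:pos] + p.core + t[pos + len(p.core) :]
            got = [a.product_len for a in ap.simulate_pcr(ap.SeqRecord("t", t), primers, model)]
            assert got == oracles.brute_products(t, primers, model)

    def test_primer_self_pair_flagged_nonspecific(self):
        core = "ACGTTGCAACGTTGCAATGG"
        template = core + "A" * 40 + ap.revcomp(core)
        amps = ap.simulate_pcr(ap.SeqRecord("t", template), [mkprimer(core, "f")])
        assert amps and all(a.nonspecific for a in amps)

    def test_sorted_by_product_length(self, packaged_panel):
        refs = ap.synthetic_reference_templates(packaged_panel)
        mix = "".join(r.seq for r in refs[:2])
        primers = list(packaged_panel.forward_primers) + [packaged_panel.reverse_primer]
        amps = ap.simulate_pcr(ap.SeqRecord("mix", mix), primers)
        lens = [a.product_len for a in amps]
        assert lens == sorted(lens)


class TestVerifyPanel:
    def test_packaged_panel_passes_with_printed_bands(self, packaged_panel, packaged_ref_aln):
        report = ap.verify_panel(packaged_panel, packaged_ref_aln)
        assert report.passed, report.failures
        assert sorted(report.table["product_len"]) == [238, 365, 502, 611, 706]

    def test_swapped_primers_fail_naming_both(self, packaged_panel, packaged_ref_aln):
        import dataclasses

        fps = list(packaged_panel.forward_primers)
        a, b = fps[0], fps[1]
        fps[0] = dataclasses.replace(a, target_species=b.target_species)
        fps[1] = dataclasses.replace(b, target_species=a.target_species)
        swapped = dataclasses.replace(
            packaged_panel,
            forward_primers=fps,
            expected_sizes={
                **packaged_panel.expected_sizes,
                a.target_species: packaged_panel.expected_sizes[b.target_species],
                b.target_species: packaged_panel.expected_sizes[a.target_species],
            },
        )
        report = ap.verify_panel(swapped, packaged_ref_aln)
        assert not report.passed
        text = " ".join(report.failures)
        assert a.name in text and b.name in text

    def test_stringency_relaxation_never_removes_target_bands(self, packaged_panel, packaged_ref_aln):
        strict = ap.verify_panel(packaged_panel, packaged_ref_aln, BindingModel())
        for allowed in (1, 2):
            relaxed_model = BindingModel(window_mismatches_allowed=allowed)
            relaxed = ap.verify_panel(packaged_panel, packaged_ref_aln, relaxed_model)
            strict_bands = set(zip(strict.table["record"], strict.table["primer"]))
            relaxed_bands = set(zip(relaxed.table["record"], relaxed.table["primer"]))
            assert strict_bands <= relaxed_bands


def test_virtual_gel_renders_bands_and_ladder():
    gel = virtual_gel({"lane1": [706, 238], "lane2": [611]})
    assert "#" in gel and "=" in gel
    assert "706" in gel and "238" in gel
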