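"""Driver-correlation screening, functional binning, and host affiliation."""

import numpy as np
import pytest

from pgsr.profiles import AlignmentHit
from pgsr.screening import (
    DriverSet,
    OrfAnnotation,
    affiliate_host_nt,
    affiliate_host_orf,
    bin_contig,
    find_orfs,
    screen_contigs,
)
from pgsr.sequences import NucleotideSequence, reverse_complement
from pgsr.simulate import make_composition_models, sample_genome

from .conftest import random_dna

TAXA = {
    "bact1": ("Bacteroides", "Bacteroidales"),
    "bact2": ("Alistipes", "Bacteroidales"),
    "firm1": ("Faecalibacterium", "Clostridiales"),
}


class TestScreenContigs:
    def test_driver_screened_against_itself(self):
        rng = np.random.default_rng(0)
        genome = NucleotideSequence("d1", random_dna(rng, 12_000))
        drivers = DriverSet.from_sequences([genome])
        hits = screen_contigs([genome], drivers)
        assert hits[0].r_best == 1.0 and hits[0].passed

    def test_length_gate_excludes_short_contigs(self):
        rng = np.random.default_rng(1)
        driver = NucleotideSequence("d1", random_dna(rng, 12_000))
        short = NucleotideSequence("short", random_dna(rng, 9_999))
        hits = screen_contigs([short, driver], DriverSet.from_sequences([driver]))
        assert [h.contig_id for h in hits] == ["d1"]

    def test_same_model_passes_distant_model_fails(self):
        models = make_composition_models(2, 0.9, seed=4)
        driver_seq = NucleotideSequence("drv", sample_genome(models[0], 30_000, 1).residues)
        near = NucleotideSequence("near", sample_genome(models[0], 20_000, 2).residues)
        far = NucleotideSequence("far", sample_genome(models[1], 20_000, 3).residues)
        drivers = DriverSet.from_sequences([driver_seq])
        by_id = {h.contig_id: h for h in screen_contigs([near, far], drivers)}
        assert by_id["near"].passed and by_id["near"].r_best >= 0.6
        assert not by_id["far"].passed

    def test_output_sorted_by_r_then_id(self, community, community_drivers):
        hits = screen_contigs(community.contigs, community_drivers)
        keys = [(-h.r_best, h.contig_id) for h in hits]
        assert keys == sorted(keys)

    def test_parameter_recovery_on_synthetic_community(self, community, community_drivers):
        """Planted prophage contigs are recovered with the right driver genus."""
        hits = screen_contigs(community.contigs, community_drivers)
        truth = community.truth
        dgenus = {d: g for d, (g, _) in community.driver_host.items()}
        phage = [h for h in hits if truth[h.contig_id]["label"] == "phage"]
        recovered = [h for h in phage if h.passed]
        assert len(recovered) / len(phage) >= 0.90
        correct = sum(
            dgenus[h.best_driver_id] == truth[h.contig_id]["genus"] for h in recovered
        )
        assert correct / len(recovered) >= 0.95
        chrom = [h for h in hits if truth[h.contig_id]["label"] == "non_phage"]
        distant_fp = sum(
            any(
                r >= 0.6
                for d, r in h.all_driver_r.items()
                if dgenus[d] != truth[h.contig_id]["genus"]
            )
            for h in chrom
        )
        assert distant_fp / len(chrom) <= 0.05

    def test_bad_r_min_rejected(self, community_drivers):
        rng = np.random.default_rng(2)
        c = NucleotideSequence("c", random_dna(rng, 11_000))
        with pytest.raises(ValueError):
            screen_contigs([c], community_drivers, r_min=1.01)

    def test_no_long_contig_warns_and_returns_empty(self, community_drivers):
        rng = np.random.default_rng(3)
        c = NucleotideSequence("c", random_dna(rng, 500))
        with pytest.warns(UserWarning):
            assert screen_contigs([c], community_drivers) == []


def orf(label, oid="o1", source="none"):
    return OrfAnnotation("c", oid, 1, 300, "+", label, source)


class TestBinContig:
    def test_phage_rule_on_capsid_label(self):
        fb = bin_contig("c", [orf("phage major capsid protein")])
        assert fb.category == "phage" and fb.supporting_orfs == ("o1",)

    def test_driver_homology_alone_is_phage(self):
        fb = bin_contig("c", [orf("hypothetical protein", source="driver-homology")])
        assert fb.category == "phage"

    def test_housekeeping_only_is_non_phage(self):
        fb = bin_contig(
            "c", [orf("ABC transporter", "o1"), orf("ribosomal protein L3", "o2")]
        )
        assert fb.category == "non_phage" and fb.supporting_orfs == ()

    def test_uninformative_or_empty_is_unclassified(self):
        assert bin_contig("c", []).category == "unclassified"
        assert bin_contig("c", [orf("hypothetical protein")]).category == "unclassified"

    def test_order_invariance(self):
        orfs = [
            orf("terminase large subunit", "o1"),
            orf("ABC transporter", "o2"),
            orf("hypothetical protein", "o3"),
        ]
        a = bin_contig("c", orfs)
        b = bin_contig("c", orfs[::-1])
        assert (a.category, a.supporting_orfs) == (b.category, b.supporting_orfs)

    def test_fixture_truth_reproduced_exactly(self, community, fixture_tables):
        for contig_id, orfs in fixture_tables["orfs"].items():
            fb = bin_contig(contig_id, orfs)
            assert fb.category == community.truth[contig_id]["label"]


class TestFindOrfs:
    def test_no_atg_means_no_orf(self):
        assert find_orfs(NucleotideSequence("x", "CCC" * 100)) == []

    def test_constructed_forward_orf(self):
        seq = NucleotideSequence("x", "ATG" + "GCT" * 59 + "TAA")
        (o,) = find_orfs(seq, min_aa=60)
        assert (o.start, o.end, o.strand) == (1, 183, "+")

    def test_reverse_complement_frame_symmetry(self):
        seq = NucleotideSequence("x", "ATG" + "GCT" * 59 + "TAA")
        rc = NucleotideSequence("y", reverse_complement(seq.residues))
        (o,) = find_orfs(rc, min_aa=60)
        assert (o.start, o.end, o.strand) == (1, 183, "-")

    def test_min_aa_gate(self):
        seq = NucleotideSequence("x", "ATG" + "GCT" * 58 + "TAA")
        assert find_orfs(seq, min_aa=60) == []
        assert len(find_orfs(seq, min_aa=59)) == 1


def hit(subject, pid=80.0, alen=1200, e=1e-10, bits=400.0, query="c"):
    return AlignmentHit(query, subject, pid, alen, e, bits)


class TestHostAffiliation:
    def test_single_valid_nt_hit_affiliates_genus(self):
        a = affiliate_host_nt("c", [hit("bact1")], taxon_map=TAXA)
        assert (a.taxon_genus, a.taxon_order, a.method) == (
            "Bacteroides", "Bacteroidales", "nucleotide",
        )

    def test_nt_length_gate(self):
        a = affiliate_host_nt("c", [hit("bact1", pid=95.0, alen=900)], taxon_map=TAXA)
        assert a.method == "none"

    def test_top_hit_by_bitscore_wins(self):
        hits = [hit("firm1", bits=300.0), hit("bact1", bits=400.0)]
        a = affiliate_host_nt("c", hits, taxon_map=TAXA)
        assert a.taxon_genus == "Bacteroides"

    def test_unknown_subject_warns_and_skips(self):
        with pytest.warns(UserWarning, match="missing from taxon map"):
            a = affiliate_host_nt("c", [hit("mystery")], taxon_map=TAXA)
        assert a.method == "none"

    def test_two_agreeing_orfs_affiliate_order_and_genus(self):
        hits = [hit("bact1", query="orf1", alen=100), hit("bact1", query="orf2", alen=100)]
        a = affiliate_host_orf("c", hits, taxon_map=TAXA)
        assert (a.taxon_genus, a.taxon_order, a.support) == (
            "Bacteroides", "Bacteroidales", 2,
        )

    def test_single_orf_is_not_enough(self):
        a = affiliate_host_orf("c", [hit("bact1", query="orf1")], taxon_map=TAXA)
        assert a.method == "none"

    def test_order_agreement_without_genus_agreement(self):
        hits = [hit("bact1", query="orf1"), hit("bact2", query="orf2")]
        a = affiliate_host_orf("c", hits, taxon_map=TAXA)
        assert (a.taxon_genus, a.taxon_order) == ("unaffiliated", "Bacteroidales")

    def test_fixture_nt_affiliation_is_perfect(self, community, fixture_tables):
        taxa = fixture_tables["taxon_map"]
        for contig_id, hits in fixture_tables["nt_hits"].items():
            a = affiliate_host_nt(contig_id, hits, taxon_map=taxa)
            assert a.taxon_genus == community.truth[contig_id]["genus"]
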