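import numpy as np
import pytest

from sirnakit import (
    GuideStrand,
    Transcriptome,
    ValidationError,
    expand_pool,
    longest_complementary_run,
    make_dN,
    reverse_complement,
    scan,
    scan_pool,
    seed,
)
from sirnakit.simulate import (
    FixtureSpec,
    PlantedRun,
    PlantedSeedMatch,
    gen_transcriptome,
)

from .conftest import make_transcript, random_rna
from .oracles import dp_longest_complementary_run, naive_seed_complement_count


def random_guide(rng) -> GuideStrand:
    return GuideStrand.from_string(random_rna(rng, 19))


class TestLongestComplementaryRun:
    def test_exact_target_site_scores_19(self, table1):
        g = table1["match_0N"]
        t = make_transcript("AUGC" * 5 + reverse_complement(g.core).residues + "GCAU" * 5)
        length, positions = longest_complementary_run(g, t)
        assert length == 19
        assert positions == [21]

    def test_planted_13mer_of_guide_positions_4_to_16(self, table1):
        g = table1["match_0N"]
        spec = FixtureSpec(seed=2, n_transcripts=1, utr3_fraction=0.0,
                           planted_runs=(PlantedRun(0, 13, guide_start=4),))
        tx, manifest = gen_transcriptome(spec, g)
        t = next(iter(tx))
        length, positions = longest_complementary_run(g, t)
        assert length == 13
        assert manifest["planted_runs"][0]["position"] in positions

    def test_no_complementary_base_scores_zero(self):
        g = GuideStrand.from_string("ACGC" * 4 + "ACG")  # no U anywhere
        t = make_transcript("A" * 50)  # A pairs only with U
        assert longest_complementary_run(g, t) == (0, [])

    def test_degenerate_guide_rejected(self, table1):
        t = make_transcript("ACGU" * 10)
        with pytest.raises(ValidationError, match="concrete"):
            longest_complementary_run(table1["match_sN"], t)

    def test_agrees_with_dp_oracle_on_1000_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            g = random_guide(rng)
            t = make_transcript(random_rna(rng, int(rng.integers(19, 120))))
            length, _ = longest_complementary_run(g, t)
            assert length == dp_longest_complementary_run(
                t.sequence.residues, str(g)
            )


class TestScan:
    def make_fixture(self, guide, runs, seed_matches=(), n=6, fx_seed=9):
        spec = FixtureSpec(
            seed=fx_seed, n_transcripts=n,
            planted_runs=tuple(runs), planted_seed_matches=tuple(seed_matches),
        )
        return gen_transcriptome(spec, guide)

    def test_single_target_gene_passes(self, table1):
        g = table1["match_0N"]
        tx, _ = self.make_fixture(g, [PlantedRun(0, 19)])
        r = scan(g, tx)
        assert r.offtarget_genes == {"GENE1"}
        assert r.passes_gene_filter  # 1 < 2

    def test_two_planted_decoys_fail_the_filter(self, table1):
        g = table1["match_0N"]
        tx, _ = self.make_fixture(
            g, [PlantedRun(0, 19), PlantedRun(1, 13), PlantedRun(2, 13)]
        )
        r = scan(g, tx)
        assert r.offtarget_genes == {"GENE1", "GENE2", "GENE3"}
        assert not r.passes_gene_filter

    def test_exact_12mer_is_not_counted(self, table1):
        g = table1["match_0N"]
        tx, _ = self.make_fixture(g, [PlantedRun(0, 12), PlantedRun(1, 13)])
        r = scan(g, tx)
        assert r.offtarget_genes == {"GENE2"}  # 12 is not > 12

    def test_exclude_gene_drops_the_intended_target(self, table1):
        g = table1["match_0N"]
        tx, _ = self.make_fixture(g, [PlantedRun(0, 19)])
        with_target = scan(g, tx)
        without = scan(g, tx, exclude_gene="GENE1")
        assert len(without.offtarget_genes) == len(with_target.offtarget_genes) - 1

    def test_raising_threshold_never_adds_genes(self, table1):
        g = table1["match_0N"]
        tx, _ = self.make_fixture(
            g, [PlantedRun(0, 19), PlantedRun(1, 14), PlantedRun(2, 13)]
        )
        sizes = [
            len(scan(g, tx, run_threshold=th).offtarget_genes)
            for th in range(10, 20)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_transcriptome_is_an_error(self, table1):
        with pytest.raises(ValidationError, match="empty"):
            scan(table1["match_0N"], Transcriptome([]))


class TestSeedComplementFrequency:
    def test_planted_seed_matches_counted_per_transcript(self, table1):
        g = table1["match_0N"]
        spec = FixtureSpec(
            seed=13, n_transcripts=5,
            planted_seed_matches=(PlantedSeedMatch(0), PlantedSeedMatch(3)),
        )
        tx, _ = gen_transcriptome(spec, g)
        r = scan(g, tx)
        assert r.scf_count >= 2
        assert r.scf_fraction == r.scf_count / 5

    def test_scf_equals_naive_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(77)
        for fx in range(20):
            g = random_guide(rng)
            spec = FixtureSpec(seed=fx, n_transcripts=8, length_range=(100, 300))
            tx, _ = gen_transcriptome(spec)
            r = scan(g, tx)
            utrs = [
                t.sequence.subseq(*t.utr3).residues for t in tx if t.utr3
            ]
            assert r.scf_count == naive_seed_complement_count(str(g), utrs)

    def test_seed_probe_is_reverse_complement_of_seed(self, table1):
        g = table1["match_0N"]
        probe = reverse_complement(seed(g)).residues
        t = make_transcript("A" * 40 + probe + "A" * 13, utr3=(31, 60))
        tx = Transcriptome([t])
        assert scan(g, tx).scf_count == 1
        # same probe outside the UTR does not count
        t2 = make_transcript(probe + "A" * 53, utr3=(31, 60))
        assert scan(g, Transcriptome([t2])).scf_count == 0


class TestScanPool:
    def test_singleton_pool_equals_member_scan(self, table1):
        g = table1["match_0N"]
        spec = FixtureSpec(seed=21, n_transcripts=4,
                           planted_runs=(PlantedRun(0, 19),))
        tx, _ = gen_transcriptome(spec, g)
        single = scan(g, tx)
        pooled = scan_pool(expand_pool(g), tx)
        assert pooled.offtarget_genes == single.offtarget_genes
        assert pooled.scf_count == single.scf_count

    def test_dn_pool_union_catches_member_specific_decoy(self, table1):
        g = table1["match_0N"]
        dn_pool = expand_pool(make_dN(table1["match_0N"]))
        # 13-nt decoy spanning guide positions 2-14 of a pool member whose
        # base at position 2 differs from the Match: the Match itself only
        # sees a 12-nt run there (not counted), the member sees 13
        member = next(m for m in dn_pool if str(m)[1] != str(g)[1])
        spec = FixtureSpec(seed=22, n_transcripts=4,
                           planted_runs=(PlantedRun(1, 13, guide_start=2),))
        tx, _ = gen_transcriptome(spec, member)
        r_member_only = scan(g, tx)
        r_pool = scan_pool(dn_pool, tx)
        assert "GENE2" in r_pool.offtarget_genes
        assert "GENE2" not in r_member_only.offtarget_genes

    def test_pool_scf_is_max_over_members(self, table1):
        dn_pool = expand_pool(table1["match_dN"])
        spec = FixtureSpec(seed=23, n_transcripts=6)
        tx, _ = gen_transcriptome(spec)
        r_pool = scan_pool(dn_pool, tx)
        assert r_pool.scf_count == max(scan(m, tx).scf_count for m in dn_pool)
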